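"""Score fruit quality by TOPSIS and normalize the index within the cohort.

Builds a small cohort of grape plots with their single fruit weight (g),
total soluble solids (%) and firmness (g), scores each plot's closeness to
the ideal quality profile with the standard SFW/TSS/FF weights, and prints
the index: 1 means best-on-everything, 0 worst; fqi_norm rescales the
cohort to [0, 1] for diagnosis.
"""

import pandas as pd

from vinefert import fqi_table

quality = pd.DataFrame(
    {
        "plot": ["A", "B", "C", "D", "E"],
        "SFW": [4.77, 5.09, 4.73, 4.47, 4.98],
        "TSS": [18.11, 18.63, 18.67, 20.10, 18.22],
        "FF": [412.62, 436.88, 455.11, 380.42, 408.18],
    }
)

scored = fqi_table(quality)
print(scored.round(4).to_string(index=False))
print(
    "\nPlot", scored.loc[scored["rank"] == 1, "plot"].iloc[0],
    "is closest to the ideal quality profile; fqi_norm spreads the cohort over [0, 1].",
)
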