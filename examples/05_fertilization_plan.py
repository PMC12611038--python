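"""Soil-test-driven precision fertilization plan with a physical blend.

Takes one soil test per growth stage (mg/g for each oxide nutrient), runs
the piecewise dose model — zero wherever the soil already sits at or above
the sufficiency bound, otherwise a linear response scaled by expected
yield through the fruit uptake share — and converts the annual totals into
a non-negative least-squares blend of real fertilizer products.
"""

import pandas as pd

from vinefert import annual_plan, solve_blend

soil_tests = pd.DataFrame(
    {
        "N": [0.20, 0.30, 0.50, 0.40, 0.80],  # last stage N above its bound
        "P2O5": [0.50, 0.90, 0.70, 1.00, 0.60],
        "K2O": [0.60, 0.70, 0.50, 0.60, 0.55],
        "CaO": [4.00, 5.00, 4.50, 5.00, 4.80],
        "MgO": [0.60, 0.70, 0.65, 0.70, 0.68],
    },
    index=pd.Index(["GS", "IFS", "EBS", "VS", "MS"], name="stage"),
)

plan = annual_plan(soil_tests, ey=3000.0)
print("per-stage recommended doses (kg per 1500 kg yield unit):")
print(plan.round(3).to_string())

totals = plan["pfa_kg"].groupby(level="oxide").sum()
print("\nannual totals:", totals.round(2).to_dict())

blend = solve_blend(totals)
print("\nphysical blend (kg of product):")
print(blend[blend["product_kg"] > 1e-9].round(2).to_string())
print("residual per nutrient:", {k: round(v, 3) for k, v in blend.attrs["residual"].items()})
print("\nStages already inside the sufficiency range receive nothing for that nutrient.")
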