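"""Derive a nutrient sufficiency range with the CND cutoff machinery.

Generates a cohort of 80 plot-years in which the top 20% by quality carry
a planted nutrient window, builds the cumulative variance-ratio curve,
fits the cubic, and reads the quality cutoff off its inflection point;
plots at or above the cutoff form the high-quality reference population
whose min–max nutrient interval is the sufficiency (optimum) range.
"""

from vinefert import cumulative_variance_function, fit_cubic, generate_planted_window
from vinefert.cnd import optimum_range, select_high_subpop

cohort, boundary, window = generate_planted_window(seed=7)
points = cumulative_variance_function(
    cohort["value"].to_numpy(), cohort["fqi_norm"].to_numpy()
)
fit = fit_cubic(points, variable="demo_nutrient")

print(f"cubic fit: F = {fit.A:.2f}X^3 + {fit.B:.2f}X^2 + {fit.C:.2f}X + {fit.D:.2f}"
      f"  (R^2 = {fit.r_squared:.4f})")
print(f"inflection cutoff -B/(3A) = {fit.cutoff:.4f} "
      f"(planted quality boundary {boundary:.4f})")

selected, fraction = select_high_subpop(cohort.set_index("unit")["fqi_norm"], fit.cutoff)
rng = optimum_range(cohort.set_index("unit").loc[selected.index, "value"],
                    "demo_nutrient", fit.cutoff, n_total=len(cohort))
print(f"reference population: {rng.subpop_size} plots ({fraction:.2f}% of the cohort)")
print(f"estimated sufficiency range {rng.low:.2f}-{rng.high:.2f} mg/g "
      f"(planted window {window[0]:.2f}-{window[1]:.2f})")
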