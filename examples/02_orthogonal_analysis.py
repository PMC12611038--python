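"""Range analysis of the L16(4^5) fertilization experiment.

Feeds the published five-year treatment means through the orthogonal
factor analysis: per-level means for each of the five oxide factors, the
best level per factor, the resulting optimal fertilization combination,
and the annual doses it implies (kg per hectare).
"""

from vinefert import build_design, constants, dose_lookup, level_means

design = build_design()
means = constants.treatment_means().reset_index()

for trait in ("TSS", "FQI"):
    fa = level_means(means, design, trait)
    print(f"{trait}: level means")
    print(fa.level_means.round(4).to_string())
    print(f"best combination: {fa.best_combination}\n")

combo = level_means(means, design, "FQI").best_combination
doses = dose_lookup(combo)
print(f"annual doses for {combo} (N, P2O5, K2O, CaO, MgO, kg/hm2): {doses}")
print("A zero dose means the soil already supplies that nutrient at this site.")
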