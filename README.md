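# vinefert

Nutrient diagnosis and precision fertilization modelling for facility-grown
'87-1' grape (*Vitis vinifera* L.), built for viticulture researchers and
agronomists who want the full analysis chain — from a balanced fertilization
trial to a soil-test-driven fertilizer recommendation — as reproducible,
testable Python.

## What it computes

The package implements five connected pieces of methodology:

1. **Fruit quality index (FQI) by TOPSIS.** Each plot's single fruit weight
   (SFW, g), total soluble solids (TSS, %) and fruit firmness (FF, g) are
   vector-normalized, weighted (w = 0.0470, 0.2089, 0.1778) and scored by
   closeness to the ideal profile, C = D⁻/(D⁺ + D⁻) ∈ [0, 1]; within a
   cohort the index is min–max normalized to [0, 1].
2. **L16(4⁵) orthogonal factor analysis.** Five oxide factors (N, P₂O₅,
   K₂O, CaO, MgO) at four annual doses each over 16 treatments: per-level
   trait means, ranges, best-level combinations such as `N3P1K2Ca1Mg2`, and
   per-factor F statistics with the replicate-level residual of the
   saturated main-effects ANOVA.
3. **CND cutoffs and optimum ranges.** For each diagnostic nutrient
   variable, units are ranked by normalized FQI; every admissible
   high/low split is scored by the variance ratio Var(top)/Var(rest); the
   cumulative, 100-normalized curve F(X) is fitted with a cubic
   AX³ + BX² + CX + D whose inflection Y = −B/(3A) is the quality cutoff.
   The min–max nutrient interval over the units at or above the cutoff is
   the sufficiency (optimum) range.
4. **Stage-wise demand accounting.** Whole-plant nutrient content
   AWP = Σ (tissue concentration × tissue dry mass), inter-stage demand
   DTS = AWP_later − AWP_earlier, and stage shares RTS = DTS/DTS_season,
   plus uptake per 1000 kg fruit and the fruit-to-whole-plant ratio FR.
5. **Precision fertilization (PFA).** Per growth interval and nutrient, a
   linear soil-test response y = ax + b (calibrated to a 1500 kg yield
   unit) gated by the sufficiency bound:
   PFA = (1 − FR)(ax + b) + FR·(EY/1500)(ax + b) if x < X_max, else 0 —
   with a non-negative least-squares solver that converts the plan into a
   blend of physical fertilizer products.

A calibrated synthetic-data generator (`vinefert.synthetic`) emulates the
16-treatment × 5-year experiment and the 7-stage destructive-harvest
series, so every stage of the analysis is testable end to end without any
field data.

## Worked example

Deriving a sufficiency range from a cohort with a planted high-quality
nutrient window (`examples/03_cnd_cutoffs.py`):

```
cubic fit: F = -134.96X^3 + 319.24X^2 + -296.05X + 110.76  (R^2 = 1.0000)
inflection cutoff -B/(3A) = 0.7885 (planted quality boundary 0.8000)
reference population: 17 plots (21.25% of the cohort)
estimated sufficiency range 8.85-11.20 mg/g (planted window 8.80-11.20)
```

The cubic's inflection recovers the quality boundary that separates the
planted high-FQI sub-population (top 20%), and the min–max interval over
that reference population recovers the planted nutrient window.

Range analysis of the published trial means (`examples/02_orthogonal_analysis.py`)
prints per-level means for each factor and concludes:

```
best combination: N3P1K2Ca1Mg2
annual doses for N3P1K2Ca1Mg2 (N, P2O5, K2O, CaO, MgO, kg/hm2): (375.0, 0.0, 168.8, 0.0, 70.5)
```

— i.e. 375 kg/hm² N and moderate K₂O and MgO, with no added P or Ca at
this site. The other examples cover quality scoring, demand accounting,
fertilization planning and the full pipeline (`vinefert run-all` on the
command line, or `vinefert.pipeline.run_all` from Python).

## Layout

- `src/vinefert/` — library modules: `topsis`, `orthogonal`, `cnd`,
  `demand`, `fertilization`, `synthetic`, `pipeline`, `constants`, `cli`
- `examples/` — one short narrative script per capability
- `tests/` — unit, property and end-to-end acceptance tests
- `docs/methods.md` — the models, calibration and numerical choices in detail
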