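# Methods

This note documents the models implemented in `vinefert`, the calibration
of the synthetic-data generator, and the numerical and design choices made
where the methodology left them open.

## Fruit quality index

The quality index is the TOPSIS closeness coefficient over three benefit
criteria: single fruit weight (g), total soluble solids (%) and fruit
firmness (g puncture force). Each criterion column of the decision matrix
is vector-normalized (divided by its Euclidean norm), multiplied by the
fixed weights (0.0470, 0.2089, 0.1778), and each alternative is scored by
C = D⁻/(D⁺ + D⁻), its Euclidean distance to the per-criterion anti-ideal
relative to the ideal. The weights are exogenous constants used exactly as
given; their sum (0.4337) is not renormalized because C is invariant to a
common rescaling of the weights. Vector normalization is the classical
choice for this method; a min–max variant is available for sensitivity
checks. If all alternatives are identical, D⁺ = D⁻ = 0 and the score is
defined as 0.5 with a warning.

Cohort handling: TOPSIS is a relative method, so the index is computed
within an analysis cohort. The pipeline default pools all treatment-years
into one cohort (80 units for the standard 16 × 5 design); per-year
scoring is available through the `cohort` option. The normalized index
`fqi_norm = (C − min C)/(max C − min C)` is likewise per cohort and is
undefined (an error) when all scores are equal.

## Orthogonal factor analysis

The L16(4⁵) array assigns five factors at four levels to 16 treatments so
that every level appears four times and every factor pair forms a complete
4 × 4 Latin structure. Doses are stored at the defining precision (level 4
is 3/2 × level 3, so the K₂O/CaO level-4 dose is 506.25 kg/hm², displayed
as 506.3).

Range analysis computes level means from *treatment means* (each of the
four treatments carrying a level enters with equal weight), so published
level rows are reproducible from published treatment rows; a
replicate-weighted variant is available. The best level maximizes the
level mean; ties resolve to the lowest level index with a warning.

F statistics use the saturated main-effects decomposition: with 15 of the
15 between-treatment degrees of freedom taken by the five factors, factor
sums of squares are computed from level means over all replicate
observations, and the error stratum is the pooled within-treatment
(replicate × year) residual. This is the standard orthogonal-table ANOVA
when the original error stratum is unreported; a year-blocked variant
would be a straightforward extension but is not needed by any downstream
step. LSD letters use the pooled one-way MSE with two-sided t critical
values and an insert-and-absorb compact letter display.

## CND cutoffs

For one diagnostic variable measured on n units with normalized quality
scores, the units are sorted by score descending and every admissible head
size j (j from m_min to n − m_min, splits never separating tied scores) is
scored by the variance ratio V_j = Var(top j)/Var(rest), sample variances
with the n − 1 denominator. The cumulative function
F_j = 100 · Σ_{i≤j} V_i / Σ V_i against X_j (the score of the j-th unit)
is fitted by ordinary least squares with a cubic; the zero of its second
derivative, Y = −B/(3A), is the cutoff. Units with score ≥ Y form the
high-quality reference sub-population and the min–max interval of the
nutrient over that sub-population is its sufficiency (optimum) range.

Choices and edge cases:

- m_min = 3 by default (a variance needs two points; three adds
  stability).
- Orientation Var(top)/Var(rest) reproduces curves that accumulate toward
  100 as the score decreases; the reciprocal is available.
- Splits with a zero-variance subgroup are skipped with a warning; if all
  are skipped the curve is undefined.
- A numerically vanishing cubic coefficient (|A| ≤ 1e−10 relative to the
  other coefficients) leaves the cutoff undefined with a warning rather
  than producing an arbitrary inflection.
- R² is 1 − SS_res/SS_tot about the mean.
- The *communal* cutoff across the plant diagnostic variables is the
  maximum defined cutoff — the most stringent plant cutoff defines the
  shared reference sub-population used for cross-variable ranges.
- Diagnostic tissue selection picks, per element, the stage × tissue with
  the smallest coefficient of variation (100·SD/mean, sample SD) across
  experimental units.

## Demand accounting

Whole-plant content at a stage is AWP = Σ_tissues concentration (mg/g) ×
dry mass (g) / 1000, in grams per tree over the seven harvested tissues
(roots, trunk, main stem, shoot, leaves, petioles, inflorescences/fruit).
Inter-stage demand DTS is the signed AWP difference — negative values
(remobilization or leaf fall) are retained, and stage shares RTS are
computed on signed values so they telescope to exactly 100% over the
season; an absolute-value variant exists for exploratory use. Fruit
harvested at maturation is credited into the final (leaf-fall) stage total
before differencing, so the crop's export counts toward season demand.
Uptake per 1000 kg fruit is AWP_season/yield, and FR is the fruit share of
season uptake. When several years are available, per-year summaries are
computed first and then averaged.

## Precision fertilization

Per growth interval and oxide nutrient, the base dose is a linear response
y = a·x + b to the soil test x (mg/g) at the interval's start stage, with
a < 0 for every shipped model. The recommended amount is

    PFA = (1 − FR)·(a·x + b) + FR·(EY/1500)·(a·x + b)   if x < X_max
    PFA = 0                                             if x ≥ X_max

where EY is expected yield (kg) against the 1500 kg calibration unit and
FR the per-nutrient fruit uptake share (defaults N 0.2531, P₂O₅ 0.1775,
K₂O 0.4465, CaO 0.1640, MgO 0.1795). X_max is the upper bound of the
sufficiency range of the start-stage *soil* variable (plant ranges are
diagnostic only). Each stage re-tests the soil and re-applies the gate
independently, so fertilization stops for any nutrient whose supply has
reached sufficiency. A negative base dose (rich soil still below X_max) is
floored at zero with a warning: the gate formally covers only x ≥ X_max,
and a negative fertilizer amount has no physical meaning. The dose unit is
the 1500 kg yield unit of the model's calibration; an area-basis
conversion is left to the caller since the models' area basis is not
defined by their coefficients.

Annual doses can be split over the five intervals by demand ratios (two
constant sets ship: the stage proportions measured in this package's
constants table, and the literature ratios used by the '5416' field
scheme; they differ and are kept separate by provenance). The blend solver
finds non-negative product masses minimizing the squared deviation of
delivered oxide nutrients from the targets (non-negative least squares)
and reports delivered amounts and residuals explicitly.

## Synthetic-data generator

The generator emulates the study design so the pipeline is testable
without field data. All draws come from `numpy.random.default_rng`
substreams spawned in a fixed order (quality, plant, soil, harvest) from
one seed, giving bit-identical reruns and independently regenerable parts.

**Quality traits** follow an additive model: grand mean + factor-level
effects + year shift + Normal(0, σ) noise, truncated at a trait floor
(with a warning if the floor is hit in more than 1% of draws). Default
grand means, per-trait noise SDs and factor-level effects are calibrated
to the published treatment table: effects are the published level-mean
deviations from the grand mean, and noise SDs are the mean within-treatment
SDs (≈0.49 g SFW, 1.41 % TSS, 43.6 g FF). Year effects are fixed additive
shifts (a symmetric ramp scaled to half the noise SD), reflecting reported
inter-annual variability without modelling interactions.

**Concentrations** are baseline + slope × applied dose of the matching
oxide, times mean-one log-normal noise (σ² = ln(1 + CV²)), which keeps all
values positive. Soil baselines sit at the midpoints of the published
optimum ranges so both sufficient and deficient units occur; plant
baselines follow the published tissue dynamics, with the five diagnostic
variables centered inside their optimum ranges and given lower relative
noise (CV 0.10 vs 0.25) so the CV-based tissue selection singles them out.
Default dose responses move a soil variable ~30% of baseline (plant ~15%)
at the top dose.

**Harvest series**: dry masses follow monotone per-tissue growth profiles
(fruit grows until maturation and is harvested before leaf fall); the
per-element whole-plant content trajectory is constructed from the
packaged stage-demand proportions (the seed-development stage takes half
of the end-bloom→veraison increment) with season totals set by the
packaged uptake-per-1000 kg constants at a 10 kg/tree yield and a
germination-stage reserve of 40% of season demand. Fruit concentrations
are constant per element so the fruit's season share equals the packaged
fruit-uptake constants. With zero noise, the demand accounting therefore
recovers those constants identically — which is the point: the generator
encodes the accounting identities, and the tests verify the code
reproduces them.

**Planted sufficiency window** (`generate_planted_window`): the cohort for
end-to-end cutoff recovery plants the *diagnostic signature* of a
sufficiency window — the top-vs-rest variance ratio is a quadratic in the
quality score with its minimum at the top-q boundary (base 1, depth 8),
which is exactly the shape implied by the cubic curves this method fits
(the magnitude of the fitted cubic's slope, |3AX² + 2BX + C|, is a
quadratic with vertex at −B/(3A)). Scores are evenly spaced; nutrient
values are the window center plus alternating-sign offsets whose squared
magnitudes solve the split-wise variance-ratio recursion, with 10%
relative magnitude jitter. Under these conditions the fitted inflection
recovers the planted boundary with median error ~0.002 and the reference
population's min–max interval overlaps ≥80% of the planted window
essentially always; "covers the planted window" is defined as ≥80%
overlap because the min–max of a finite sample drawn inside a window
cannot strictly contain it.

What the generator does *not* emulate: weather-driven mechanisms behind
year effects (only additive shifts), nutrient interactions and carryover
between seasons, measurement-protocol artifacts, and irregular score
spacing in the planted-window cohort (with irregularly spaced scores the
split-wise cumulative curve is warped by score clustering and the
inflection estimator becomes noticeably noisier). Passing tests therefore
demonstrate correctness of the computations and recoverability of planted
structure under the stated conditions, not robustness to every feature of
real survey data.

## Problem sizes and tolerances

Tests run the standard 16 × 5 × 3 experiment (240 quality records, 80
treatment-year units), 100-seed recovery loops for the cutoff and
orthogonal analyses, and cohorts of 80 units for all CND properties —
matching the design sizes the methodology targets. Exact identities
(telescoping, conservation, oracle equivalence) are asserted at 1e−8 to
1e−12; published values at their printed precision; stochastic recoveries
at the tolerances stated alongside each property (e.g. cutoff within ±0.1
of the boundary in median over 100 seeds).
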