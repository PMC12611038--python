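"""Seeded synthetic datasets emulating the facility-grape fertilization study.

The real experiment applied an L16(4^5) design of N/P2O5/K2O/CaO/MgO doses to
facility-grown '87-1' grape over five seasons (3 replicates per treatment),
sampled tissue and soil nutrients per treatment-year, and destructively
harvested trees at seven phenological stages.  This module generates data
with the same structure and with statistics calibrated to the published
summary tables, so every downstream analysis is testable end to end:

* quality traits: additive model, trait = grand mean + Σ factor-level
  effects + year shift + Gaussian noise (default effects are the published
  level-mean deviations, default noise the published within-treatment SDs);
* tissue/soil concentrations: baseline + linear dose response, with
  multiplicative log-normal noise (concentrations stay positive), baselines
  centered inside the published optimum ranges;
* destructive-harvest series: monotone growth profiles per tissue, with
  whole-plant nutrient contents following the published stage-demand
  proportions and season uptake per 1000 kg fruit, so the demand
  accounting recovers those constants by construction.

All draws come from ``numpy.random.default_rng`` substreams spawned from
one scenario seed (streams, in order: quality, plant nutrients, soil
nutrients, harvest), so a fixed seed gives bit-identical output and each
generator can be re-run independently.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import constants
from .constants import (
    ELEMENTS,
    FACTOR_TO_ELEMENT,
    FACTORS,
    HARVEST_STAGES,
    HARVEST_TISSUES,
    PLANT_STAGES,
    PLANT_TISSUES,
    QUALITY_TRAITS,
    SOIL_STAGES,
)
from .orthogonal import DesignTable, build_design

__all__ = [
    "ExperimentScenario",
    "default_factor_effects",
    "default_baselines",
    "generate_quality",
    "generate_nutrients",
    "generate_harvest_series",
    "generate_planted_window",
    "mean_tree",
]

_TISSUE_TAG = {"fruit": "F", "leaf": "L", "petiole": "P"}

#: Final dry masses per tissue (g per tree) used by the harvest generator.
_TISSUE_FINAL_MASS = {
    "roots": 2500.0,
    "trunk": 2000.0,
    "main stem": 1200.0,
    "shoot": 900.0,
    "leaves": 1100.0,
    "petioles": 150.0,
    "fruit": 1500.0,
}

#: Fraction of final mass reached at each stage (non-fruit tissues).
_MASS_PROFILE = (0.35, 0.45, 0.55, 0.70, 0.85, 0.95, 1.0)

#: Fruit mass fractions: none at germination, harvested before leaf fall.
_FRUIT_PROFILE = (0.004, 0.02, 0.05, 0.20, 0.50, 1.0, 0.0)

#: Non-diagnostic plant baselines (mg·g⁻¹), loosely following the published
#: tissue dynamics (leaf N high, petiole K high at veraison, fruit Mg
#: falling toward maturation).
_PLANT_BASELINES = {
    ("FBS", "fruit"): {"N": 18.0, "P": 4.5, "K": 22.86, "Ca": 65.88, "Mg": 13.20},
    ("FBS", "leaf"): {"N": 9.854, "P": 3.2, "K": 12.0, "Ca": 45.0, "Mg": 4.0},
    ("FBS", "petiole"): {"N": 8.0, "P": 4.0, "K": 19.0, "Ca": 49.0, "Mg": 6.0},
    ("VS", "fruit"): {"N": 10.0, "P": 3.0, "K": 18.0, "Ca": 24.9, "Mg": 8.0},
    ("VS", "leaf"): {"N": 24.0, "P": 2.8, "K": 13.0, "Ca": 52.0, "Mg": 4.5},
    ("VS", "petiole"): {"N": 7.0, "P": 5.11, "K": 38.2, "Ca": 50.0, "Mg": 7.0},
    ("MS", "fruit"): {"N": 8.0, "P": 2.5, "K": 16.0, "Ca": 26.6, "Mg": 5.6},
    ("MS", "leaf"): {"N": 20.0, "P": 2.4, "K": 11.0, "Ca": 58.0, "Mg": 4.2},
    ("MS", "petiole"): {"N": 6.5, "P": 3.5, "K": 34.4, "Ca": 48.8, "Mg": 6.5},
}

#: Diagnostic variables (stage, tissue) per element, matching the published
#: cumulative-variance table; their relative noise defaults lower than the
#: rest so the CV-based tissue selection singles them out.
DIAGNOSTIC_PLANT_VARIABLES = {
    "N": ("FBS", "leaf"),
    "P": ("VS", "petiole"),
    "K": ("FBS", "fruit"),
    "Ca": ("FBS", "fruit"),
    "Mg": ("FBS", "fruit"),
}


def default_factor_effects() -> dict[str, dict[str, tuple[float, float, float, float]]]:
    """Per-trait additive factor-level effects calibrated to the published level means.

    The effect of level l of factor f on a trait is the published level
    mean minus the grand mean, i.e. the main-effect estimate of the
    orthogonal analysis applied to the published treatment means.
    """
    design = build_design()
    tm = constants.treatment_means()
    effects: dict[str, dict[str, tuple[float, ...]]] = {}
    for trait in QUALITY_TRAITS:
        grand = tm[trait].mean()
        per_factor = {}
        for f in FACTORS:
            lv = design.levels[f]
            per_factor[f] = tuple(
                float(tm[trait][lv[lv == level].index].mean() - grand) for level in (1, 2, 3, 4)
            )
        effects[trait] = per_factor
    return effects


def default_baselines() -> dict[str, float]:
    """Baseline concentrations (mg·g⁻¹) for every plant and soil variable.

    Soil baselines sit at the midpoint of the published optimum range so
    both sufficient and deficient treatment-years occur; plant baselines
    follow the published tissue dynamics with the diagnostic variables
    centered inside their optimum ranges.
    """
    out: dict[str, float] = {}
    for (stage, tissue), per_el in _PLANT_BASELINES.items():
        for el, v in per_el.items():
            out[f"{stage}_{_TISSUE_TAG[tissue]}_{el}"] = v
    cub = constants.cubic_table()
    for stage in SOIL_STAGES:
        for el in ELEMENTS:
            row = cub.loc[f"{stage}_{el}"]
            out[f"{stage}_{el}"] = float((row["range1_low"] + row["range1_high"]) / 2)
    return out


def _default_noise_sd() -> dict[str, float]:
    sds = constants.treatment_sds()
    return {t: float(sds[t].mean()) for t in QUALITY_TRAITS}


def _default_grand_means() -> dict[str, float]:
    tm = constants.treatment_means()
    return {t: float(tm[t].mean()) for t in QUALITY_TRAITS}


@dataclass
class ExperimentScenario:
    """Parameters of one synthetic run of the study.

    Quality traits use additive Gaussian noise; concentrations use
    multiplicative log-normal noise with the given coefficient of
    variation.  ``nutrient_response`` maps variable label → concentration
    slope per kg·hm⁻² of the matching oxide dose; the default gives every
    soil variable a response moving it ~30% of baseline at the top dose
    (~15% for plant variables).
    """

    seed: int = 0
    n_years: int = 5
    n_reps: int = 3
    grand_means: dict[str, float] = field(default_factory=_default_grand_means)
    factor_effects: dict[str, dict[str, tuple[float, float, float, float]]] = field(
        default_factory=default_factor_effects
    )
    year_effect_scale: float = 0.5  # year shifts as a multiple of noise_sd
    noise_sd: dict[str, float] = field(default_factory=_default_noise_sd)
    trait_floor: dict[str, float] = field(
        default_factory=lambda: {"SFW": 0.5, "TSS": 5.0, "FF": 50.0}
    )
    baseline_concentrations: dict[str, float] = field(default_factory=default_baselines)
    nutrient_response: dict[str, float] | None = None
    concentration_cv: dict[str, float] | float = 0.25
    diagnostic_cv: float = 0.10  # relative noise of the diagnostic plant variables
    # destructive-harvest calibration
    yield_kg: float = 10.0  # fresh fruit yield per tree
    uptake_per_1000kg: dict[str, float] = field(
        default_factory=lambda: dict(constants.TOTAL_UPTAKE_PER_1000KG)
    )
    fruit_uptake_per_1000kg: dict[str, float] = field(
        default_factory=lambda: dict(constants.FRUIT_UPTAKE_PER_1000KG)
    )
    reserve_fraction: float = 0.4  # AWP at germination as a share of season demand
    harvest_cv: float = 0.0
    n_trees: int = 3

    def __post_init__(self) -> None:
        if self.n_years < 1 or self.n_reps < 1 or self.n_trees < 1:
            raise ValueError("n_years, n_reps and n_trees must be >= 1")
        if any(sd < 0 for sd in self.noise_sd.values()):
            raise ValueError("noise_sd must be non-negative")
        bad = {k: v for k, v in self.baseline_concentrations.items() if v <= 0}
        if bad:
            raise ValueError(f"baseline concentrations must be positive: {sorted(bad)[:5]}")
        if self.nutrient_response is None:
            self.nutrient_response = self._default_response()

    def _default_response(self) -> dict[str, float]:
        resp = {}
        for var, base in self.baseline_concentrations.items():
            el = var.split("_")[-1]
            oxide = {v: k for k, v in FACTOR_TO_ELEMENT.items()}[el]
            max_dose = constants.LEVEL_DOSES[oxide][-1]
            frac = 0.30 if var.count("_") == 1 else 0.15  # soil vs plant label
            resp[var] = frac * base / max_dose
        return resp

    def streams(self) -> dict[str, np.random.Generator]:
        """Named substreams spawned deterministically from the scenario seed."""
        ss = np.random.SeedSequence(self.seed)
        children = ss.spawn(4)
        names = ("quality", "plant", "soil", "harvest")
        return {n: np.random.default_rng(c) for n, c in zip(names, children)}

    def cv_of(self, variable: str) -> float:
        if isinstance(self.concentration_cv, dict):
            return self.concentration_cv.get(variable, 0.25)
        el = variable.split("_")[-1]
        parts = variable.split("_")
        if len(parts) == 3:  # plant variable STAGE_T_EL
            stage_tissue = DIAGNOSTIC_PLANT_VARIABLES[el]
            tag = f"{stage_tissue[0]}_{_TISSUE_TAG[stage_tissue[1]]}_{el}"
            if variable == tag:
                return self.diagnostic_cv
        return float(self.concentration_cv)

    def year_effects(self, trait: str) -> np.ndarray:
        """Fixed additive year shifts, symmetric around zero."""
        if self.n_years == 1:
            return np.zeros(1)
        ramp = np.linspace(-1.0, 1.0, self.n_years)
        return ramp * self.year_effect_scale * self.noise_sd[trait]


def generate_quality(
    scenario: ExperimentScenario, design: DesignTable | None = None
) -> pd.DataFrame:
    """Per-plot quality records: 16 treatments × n_years × n_reps rows.

    Trait value = grand mean + Σ factor-level effects + year shift +
    Normal(0, noise_sd), redrawn (truncated) at the trait floor; if the
    floor is hit in more than 1% of draws a warning flags a mis-calibrated
    scenario.
    """
    if design is None:
        design = build_design()
    rng = scenario.streams()["quality"]
    rows = []
    floor_hits = total_draws = 0
    for treatment in design.treatments:
        levels = design.levels.loc[treatment]
        for year in range(1, scenario.n_years + 1):
            for rep in range(1, scenario.n_reps + 1):
                rec = {"treatment": treatment, "year": year, "rep": rep}
                for trait in QUALITY_TRAITS:
                    mean = scenario.grand_means[trait]
                    mean += sum(
                        scenario.factor_effects[trait][f][levels[f] - 1] for f in FACTORS
                    )
                    mean += scenario.year_effects(trait)[year - 1]
                    sd = scenario.noise_sd[trait]
                    val = mean + (rng.normal(0.0, sd) if sd > 0 else 0.0)
                    total_draws += 1
                    floor = scenario.trait_floor.get(trait, 0.0)
                    if val < floor:
                        floor_hits += 1
                        val = floor
                    rec[trait] = val
                rows.append(rec)
    if total_draws and floor_hits / total_draws > 0.01:
        warnings.warn(
            f"trait floor hit in {100 * floor_hits / total_draws:.1f}% of draws; "
            "scenario may be mis-calibrated",
            stacklevel=2,
        )
    return pd.DataFrame(rows)


def _lognormal_factor(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    """Mean-one multiplicative log-normal noise with the given CV."""
    if cv <= 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv**2))
    return np.exp(rng.normal(-(sigma**2) / 2.0, sigma, size))


def _dose_for(variable: str, doses: pd.Series) -> float:
    el = variable.split("_")[-1]
    oxide = {v: k for k, v in FACTOR_TO_ELEMENT.items()}[el]
    return float(doses[oxide])


def generate_nutrients(
    scenario: ExperimentScenario, design: DesignTable | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Plant and soil nutrient observations per treatment-year.

    Returns ``(plant, soil)`` tidy tables.  Plant rows cover stages
    FBS/VS/MS × tissues fruit/leaf/petiole × five elements; soil rows cover
    stages GS/IFS/EBS/VS/MS × five elements.  Concentration =
    (baseline + response × applied dose) × log-normal noise, so values stay
    positive; zero response and zero noise reproduce the baselines exactly.
    """
    if design is None:
        design = build_design()
    streams = scenario.streams()
    units = [
        (t, y) for t in design.treatments for y in range(1, scenario.n_years + 1)
    ]

    def _table(variables: list[str], rng: np.random.Generator) -> pd.DataFrame:
        rows = []
        for var in variables:
            base = scenario.baseline_concentrations.get(var)
            if base is None:
                raise ValueError(f"no baseline concentration configured for {var!r}")
            slope = scenario.nutrient_response.get(var, 0.0)
            noise = _lognormal_factor(rng, scenario.cv_of(var), len(units))
            for (treatment, year), nz in zip(units, noise):
                dose = _dose_for(var, design.doses.loc[treatment])
                value = (base + slope * dose) * nz
                rows.append(
                    {"treatment": treatment, "year": year, "variable": var, "value": value}
                )
        return pd.DataFrame(rows)

    plant_vars = [
        f"{stage}_{_TISSUE_TAG[tissue]}_{el}"
        for stage in PLANT_STAGES
        for tissue in PLANT_TISSUES
        for el in ELEMENTS
    ]
    soil_vars = [f"{stage}_{el}" for stage in SOIL_STAGES for el in ELEMENTS]

    plant = _table(plant_vars, streams["plant"])
    parts = plant["variable"].str.split("_", expand=True)
    plant["stage"], plant["element"] = parts[0], parts[2]
    plant["tissue"] = parts[1].map({v: k for k, v in _TISSUE_TAG.items()})

    soil = _table(soil_vars, streams["soil"])
    parts = soil["variable"].str.split("_", expand=True)
    soil["stage"], soil["element"] = parts[0], parts[1]
    return plant, soil


def _stage_cumfractions() -> dict[str, np.ndarray]:
    """Cumulative share of season demand reached at each harvest stage.

    The published interval proportions run GS-IFS, IFS-EBS, EBS-VS, VS-MS,
    MS-DS; the harvest series adds the seed-development stage, which takes
    half of the EBS→VS increment.
    """
    sm = constants.stage_models()
    out = {}
    for oxide in FACTORS:
        el = FACTOR_TO_ELEMENT[oxide]
        p = sm.xs(oxide, level="oxide")["proportion_pct"].reindex(constants.INTERVALS) / 100.0
        cum = {
            "GS": 0.0,
            "IFS": p["GS-IFS"],
            "EBS": p["GS-IFS"] + p["IFS-EBS"],
        }
        cum["SDS"] = cum["EBS"] + p["EBS-VS"] / 2.0
        cum["VS"] = cum["EBS"] + p["EBS-VS"]
        cum["MS"] = cum["VS"] + p["VS-MS"]
        cum["DS"] = cum["MS"] + p["MS-DS"]
        out[el] = np.array([cum[s] for s in HARVEST_STAGES])
    return out


def generate_harvest_series(scenario: ExperimentScenario) -> pd.DataFrame:
    """Destructive-harvest series: 7 stages × 7 tissues × n_trees × n_years.

    Dry masses follow monotone growth profiles per tissue; fruit grows
    until maturation and is harvested before the deciduous stage.
    Whole-plant nutrient contents are constructed to follow the published
    stage-demand proportions, with the season demand per element set by
    the per-1000 kg uptake targets and the tree yield, and the fruit's
    share set by the fruit uptake targets — so with zero noise the demand
    accounting recovers those constants identically.
    """
    rng = scenario.streams()["harvest"]
    cumfrac = _stage_cumfractions()
    demand = {
        el: scenario.uptake_per_1000kg[el] * scenario.yield_kg  # kg/1000kg × kg → g
        for el in ELEMENTS
    }
    fruit_season = {
        el: scenario.fruit_uptake_per_1000kg[el] * scenario.yield_kg for el in ELEMENTS
    }
    reserve = {el: scenario.reserve_fraction * demand[el] for el in ELEMENTS}
    fruit_conc = {
        el: fruit_season[el] * 1000.0 / _TISSUE_FINAL_MASS["fruit"] for el in ELEMENTS
    }

    rows = []
    for year in range(1, scenario.n_years + 1):
        for tree in range(1, scenario.n_trees + 1):
            for si, stage in enumerate(HARVEST_STAGES):
                masses = {}
                for tissue in HARVEST_TISSUES:
                    prof = _FRUIT_PROFILE if tissue == "fruit" else _MASS_PROFILE
                    masses[tissue] = _TISSUE_FINAL_MASS[tissue] * prof[si]
                nonfruit_mass = sum(m for t, m in masses.items() if t != "fruit")
                for el in ELEMENTS:
                    awp_target = reserve[el] + demand[el] * cumfrac[el][si]
                    fruit_awp = fruit_season[el] * _FRUIT_PROFILE[si]
                    if stage == "DS":  # crop already harvested
                        awp_target -= fruit_season[el] * _FRUIT_PROFILE[5]
                        fruit_awp = 0.0
                    nonfruit_awp = awp_target - fruit_awp
                    if nonfruit_awp <= 0:
                        raise ValueError(
                            f"harvest calibration gives non-positive non-fruit content "
                            f"for {el} at {stage}"
                        )
                    conc_nonfruit = nonfruit_awp * 1000.0 / nonfruit_mass
                    for tissue in HARVEST_TISSUES:
                        conc = fruit_conc[el] if tissue == "fruit" else conc_nonfruit
                        noise_m, noise_c = _lognormal_factor(rng, scenario.harvest_cv, 2)
                        rows.append(
                            {
                                "year": year,
                                "tree": tree,
                                "stage": stage,
                                "tissue": tissue,
                                "element": el,
                                "dry_mass": masses[tissue] * noise_m,
                                "concentration": conc * noise_c,
                            }
                        )
    return pd.DataFrame(rows)


def mean_tree(harvest: pd.DataFrame) -> pd.DataFrame:
    """Average the harvest series over years and trees to one mean tree."""
    g = harvest.groupby(["stage", "tissue", "element"], as_index=False)
    return g[["dry_mass", "concentration"]].mean()


def generate_planted_window(
    seed: int,
    n: int = 80,
    q: float = 0.2,
    center: float = 10.0,
    ratio_base: float = 1.0,
    ratio_depth: float = 8.0,
    jitter: float = 0.1,
) -> tuple[pd.DataFrame, float, tuple[float, float]]:
    """Cohort with a nutrient sufficiency window planted in the top-q quality units.

    The diagnostic signature of a sufficiency window under the
    cumulative-variance method is a top-vs-rest variance ratio that is
    smallest when the candidate reference group is exactly the true
    high-quality sub-population and grows as the split moves away in
    either direction.  This generator plants that structure directly: the
    n units get evenly spaced normalized quality scores, and nutrient
    values are the window center plus alternating-sign offsets whose
    squared magnitudes are solved so the empirical variance ratio at each
    split follows ``ratio_base + ratio_depth·(X − boundary)²`` — a
    quadratic with its minimum at the top-q boundary — up to a relative
    magnitude ``jitter``.  Units above the boundary thus sit inside a
    bounded window around the center and the split-wise variance ratio
    bottoms out exactly when the head group is the planted sub-population,
    so the fitted cubic's inflection should recover the boundary.

    Returns ``(table, boundary, window)`` where the table has columns
    unit, fqi_norm, value; ``boundary`` is the (1−q)-quantile of
    fqi_norm; and ``window`` is the planted (low, high) interval actually
    occupied by the top-q units.
    """
    if not 0 < q < 0.5:
        raise ValueError("q must be in (0, 0.5)")
    if n < 12:
        raise ValueError("need at least 12 units")
    rng = np.random.default_rng(seed)
    fqi_norm = np.linspace(0.0, 1.0, n)
    rng.shuffle(fqi_norm)  # unit order carries no information
    order = np.argsort(-fqi_norm)
    x_sorted = fqi_norm[order]
    boundary = float(np.quantile(fqi_norm, 1.0 - q))

    # target variance-ratio profile at each head size j, evaluated at the
    # score of the j-th unit
    ratio = ratio_base + ratio_depth * (x_sorted - boundary) ** 2
    ss_total = float(n)
    ss = np.zeros(n + 1)  # ss[j] = Σ squared offsets among the top j units
    for j in range(2, n - 1):
        rho = ratio[j - 1] * (j - 1) / (n - j - 1)
        ss[j] = ss_total * rho / (1.0 + rho)
    ss[1] = ss[2] / 2.0
    ss[n - 1] = ss[n - 2] + (ss_total - ss[n - 2]) / 2.0
    ss[n] = ss_total
    mags = np.sqrt(np.clip(np.diff(ss), 1e-9, None))
    mags = mags * (1.0 + jitter * rng.normal(0.0, 1.0, n))
    signs = np.where(np.arange(n) % 2 == 0, 1.0, -1.0)
    values = np.empty(n)
    values[order] = center + signs * mags

    k = int(round(q * n))
    half = float(np.abs(mags[:k]).max())
    df = pd.DataFrame(
        {"unit": [f"u{i}" for i in range(n)], "fqi_norm": fqi_norm, "value": values}
    )
    return df, boundary, (center - half, center + half)
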