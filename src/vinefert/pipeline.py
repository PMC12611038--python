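"""End-to-end orchestration: synthetic (or user) data → quality index →
orthogonal factor analysis → CND cutoffs and optimum ranges → demand
constants → fertilization plan, with every intermediate written as a tidy
CSV so each stage is diffable and independently checkable."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__, constants
from .cnd import communal_cutoff, diagnose_variable, select_diagnostic_tissue
from .demand import stage_demand_table, uptake_per_yield
from .fertilization import annual_plan
from .orthogonal import build_design, factor_f_values, level_means
from .synthetic import (
    ExperimentScenario,
    generate_harvest_series,
    generate_nutrients,
    generate_quality,
    mean_tree,
)
from .topsis import TopsisConfig, fqi_table

logger = logging.getLogger("vinefert")

__all__ = ["RunConfig", "run_all", "render_factor_report", "render_cnd_report"]


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    seed: int = 0
    out_dir: str | Path = "vinefert_out"
    scenario: ExperimentScenario | None = None
    quality_csv: str | Path | None = None
    plant_csv: str | Path | None = None
    soil_csv: str | Path | None = None
    harvest_csv: str | Path | None = None
    topsis: TopsisConfig = field(default_factory=TopsisConfig)
    cohort: str | list[str] | None = None  # TOPSIS cohort columns; None = pooled
    m_min: int = 3
    expected_yield: float = 1500.0
    cutoff_rule: str = "communal"  # or "per_variable"

    def __post_init__(self) -> None:
        synthetic = self.quality_csv is None
        if synthetic and self.scenario is None:
            self.scenario = ExperimentScenario(seed=self.seed)


def _treatment_year_quality(quality: pd.DataFrame) -> pd.DataFrame:
    """Collapse replicates to one row per treatment-year (the CND unit)."""
    keys = ["treatment", "year"]
    return quality.groupby(keys, as_index=False)[list(constants.QUALITY_TRAITS)].mean()


def run_all(config: RunConfig) -> dict[str, pd.DataFrame]:
    """Run the full analysis and write the report bundle under ``out_dir``.

    Writes quality.csv, fqi.csv, factor_report.csv, cnd_report.csv,
    demand_report.csv, plan.csv and run_log.json.  Deterministic for a
    fixed seed.  Returns the bundle as a dict of DataFrames.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    design = build_design()
    bundle: dict[str, pd.DataFrame] = {}

    # --- stage 1: data -----------------------------------------------------
    if config.quality_csv is not None:
        quality = pd.read_csv(config.quality_csv)
        if config.plant_csv is None or config.soil_csv is None:
            raise ValueError("CND diagnosis requested without plant/soil nutrient files")
        plant = pd.read_csv(config.plant_csv)
        soil = pd.read_csv(config.soil_csv)
        harvest = pd.read_csv(config.harvest_csv) if config.harvest_csv else None
    else:
        scenario = config.scenario
        quality = generate_quality(scenario, design)
        plant, soil = generate_nutrients(scenario, design)
        harvest = generate_harvest_series(scenario)
    logger.info("stage data: %d quality records, %d plant obs, %d soil obs",
                len(quality), len(plant), len(soil))
    bundle["quality"] = quality

    # --- stage 2: fruit quality index --------------------------------------
    per_unit = _treatment_year_quality(quality)
    fqi = fqi_table(per_unit, config.topsis, cohort=config.cohort)
    bundle["fqi"] = fqi
    logger.info("stage fqi: %d units scored", len(fqi))

    # --- stage 3: orthogonal factor analysis --------------------------------
    frames = []
    for trait in (*constants.QUALITY_TRAITS, "fqi"):
        source = fqi if trait == "fqi" else quality
        fa = level_means(source, design, trait)
        fv, order, _ = factor_f_values(source, design, trait)
        lm = fa.level_means.copy()
        lm["row"] = [f"L{i}" for i in lm.index]
        lm["trait"] = trait
        best = pd.DataFrame(
            [
                {"trait": trait, "row": "Best level", **fa.best_level.to_dict()},
                {"trait": trait, "row": "F value", **fv.to_dict()},
            ]
        )
        lm = pd.concat([lm.reset_index(drop=True), best], ignore_index=True)
        lm["best_combination"] = fa.best_combination
        lm["factor_order"] = order
        frames.append(lm)
    factor_report = pd.concat(frames, ignore_index=True)
    bundle["factor_report"] = factor_report

    # --- stage 4: CND diagnosis ---------------------------------------------
    unit_fqi = fqi.set_index(["treatment", "year"])["fqi_norm"]
    choice, cv_table = select_diagnostic_tissue(plant)
    bundle["cv_table"] = cv_table

    plant_wide = plant.pivot_table(
        index=["treatment", "year"], columns="variable", values="value"
    )
    soil_wide = soil.pivot_table(
        index=["treatment", "year"], columns="variable", values="value"
    )

    records = []
    plant_fits = []
    tag = {"fruit": "F", "leaf": "L", "petiole": "P"}
    for el, row in choice.iterrows():
        var = f"{row['stage']}_{tag[row['tissue']]}_{el}"
        vals = plant_wide[var]
        fit, rng1 = diagnose_variable(vals, unit_fqi.loc[vals.index], var, m_min=config.m_min)
        plant_fits.append(fit)
        records.append({"kind": "plant", "fit": fit, "range1": rng1, "values": vals})
    for var in soil_wide.columns:
        vals = soil_wide[var]
        fit, rng1 = diagnose_variable(vals, unit_fqi.loc[vals.index], var, m_min=config.m_min)
        records.append({"kind": "soil", "fit": fit, "range1": rng1, "values": vals})

    comm = communal_cutoff(plant_fits) if config.cutoff_rule == "communal" else None
    rows = []
    for rec in records:
        fit, rng1, vals = rec["fit"], rec["range1"], rec["values"]
        if comm is not None:
            _, rng2 = diagnose_variable(
                vals, unit_fqi.loc[vals.index], fit.variable, m_min=config.m_min, cutoff=comm
            )
        else:
            rng2 = rng1
        rows.append(
            {
                "variable": fit.variable,
                "kind": rec["kind"],
                "A": fit.A,
                "B": fit.B,
                "C": fit.C,
                "D": fit.D,
                "r_squared": fit.r_squared,
                "cutoff": fit.cutoff,
                "subpop_size": rng1.subpop_size,
                "subpop_fraction": rng1.subpop_fraction,
                "range1_low": rng1.low,
                "range1_high": rng1.high,
                "range2_low": rng2.low,
                "range2_high": rng2.high,
            }
        )
    cnd_report = pd.DataFrame(rows)
    cnd_report.attrs["communal_cutoff"] = comm
    bundle["cnd_report"] = cnd_report
    logger.info("stage cnd: %d variables diagnosed, communal cutoff %s",
                len(cnd_report), f"{comm:.4f}" if comm is not None else "per-variable")

    # --- stage 5: demand accounting -----------------------------------------
    if harvest is not None:
        tree = mean_tree(harvest)
        demand_report = stage_demand_table(tree).reset_index()
        season = demand_report.groupby("element")["dts"].sum()
        ms_fruit = tree[(tree["stage"] == "MS") & (tree["tissue"] == "fruit")]
        fruit_awp = (ms_fruit["concentration"] * ms_fruit["dry_mass"] / 1000.0).groupby(
            ms_fruit["element"]
        ).sum()
        scenario_yield = config.scenario.yield_kg if config.scenario else 10.0
        uptake = uptake_per_yield(season, scenario_yield, fruit_awp).reset_index()
        bundle["demand_report"] = demand_report
        bundle["uptake_report"] = uptake
        logger.info("stage demand: %d intervals × elements", len(demand_report))

    # --- stage 6: fertilization plan -----------------------------------------
    # soil tests for the plan: per-stage mean soil concentrations, mapped to
    # the oxide columns of the stage models
    soil_means = soil.groupby(["stage", "element"])["value"].mean().unstack()
    el_to_ox = {v: k for k, v in constants.FACTOR_TO_ELEMENT.items()}
    soil_tests = soil_means.rename(columns=el_to_ox).reindex(list(constants.FACTORS), axis=1)
    soil_tests = soil_tests.reindex(list(constants.SOIL_STAGES))
    plan = annual_plan(soil_tests, ey=config.expected_yield).reset_index()
    bundle["plan"] = plan
    logger.info("stage fertilize: annual totals %s",
                {k: round(v, 2) for k, v in plan.groupby("oxide")["pfa_kg"].sum().items()})

    # --- write bundle ---------------------------------------------------------
    for name in ("quality", "fqi", "factor_report", "cv_table", "cnd_report",
                 "demand_report", "uptake_report", "plan"):
        if name in bundle:
            bundle[name].to_csv(out / f"{name}.csv", index=False)
    log = {
        "package": "vinefert",
        "version": __version__,
        "seed": config.seed,
        "synthetic": config.quality_csv is None,
        "n_quality_records": len(quality),
        "communal_cutoff": comm,
        "expected_yield": config.expected_yield,
    }
    (out / "run_log.json").write_text(json.dumps(log, indent=2))
    return bundle


def render_factor_report(bundle: dict[str, pd.DataFrame]) -> str:
    """Text rendering of the factor analysis in the published table layout."""
    if "factor_report" not in bundle or bundle["factor_report"].empty:
        raise ValueError("bundle has no factor report")
    fr = bundle["factor_report"]
    lines = []
    for trait, g in fr.groupby("trait", sort=False):
        lines.append(f"== {trait} ==  best {g['best_combination'].iloc[0]}  "
                     f"order {g['factor_order'].iloc[0]}")
        cols = list(constants.FACTORS)
        lines.append("\t".join(["row"] + cols))
        for _, row in g.iterrows():
            vals = [
                f"{row[c]:.4f}" if isinstance(row[c], float) else str(row[c]) for c in cols
            ]
            lines.append("\t".join([str(row["row"])] + vals))
    return "\n".join(lines)


def render_cnd_report(bundle: dict[str, pd.DataFrame]) -> str:
    """Text rendering of the CND cutoff table (variable, cubic, R², ranges)."""
    if "cnd_report" not in bundle or bundle["cnd_report"].empty:
        raise ValueError("bundle has no CND report")
    rep = bundle["cnd_report"]
    lines = ["variable\tfunction\tR2\tcutoff\trange1\trange2"]
    for _, r in rep.iterrows():
        fn = (f"F = {r['A']:.3f}X^3 + {r['B']:.3f}X^2 + {r['C']:.3f}X + {r['D']:.3f}")
        lines.append(
            f"{r['variable']}\t{fn}\t{r['r_squared']:.4f}\t{r['cutoff']:.4f}\t"
            f"{r['range1_low']:.3f}-{r['range1_high']:.3f}\t"
            f"{r['range2_low']:.3f}-{r['range2_high']:.3f}"
        )
    return "\n".join(lines)
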