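"""Stage-wise nutrient demand accounting from destructive-harvest data.

Whole-plant nutrient content at a stage (AWP, g) sums concentration ×
dry mass over the seven harvested tissues; the demand between two stages
(DTS, g) is the AWP difference, and the stage demand ratio (RTS, %) is
each interval's DTS as a share of the full-season GS→DS demand.  Harvested
fruit removed at maturation is credited back into the final (DS) total so
the season's demand includes what the crop exported.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .constants import ELEMENTS, HARVEST_STAGES, HARVEST_TISSUES

__all__ = [
    "awp",
    "dts",
    "rts",
    "stage_demand_table",
    "uptake_per_yield",
    "UptakeSummary",
]


def awp(harvest: pd.DataFrame, value_col: str = "concentration") -> pd.Series:
    """Whole-plant nutrient content (g) per element at one stage.

    ``harvest`` is tidy with columns tissue, element, dry_mass (g) and the
    concentration column (mg·g⁻¹); rows describe one tree at one stage.
    Tissues absent from the table contribute zero (with a warning).
    """
    required = {"tissue", "element", "dry_mass", value_col}
    if not required <= set(harvest.columns):
        raise ValueError(f"harvest table needs columns {sorted(required)}")
    if (harvest["dry_mass"] < 0).any() or (harvest[value_col] < 0).any():
        raise ValueError("dry mass and concentrations must be non-negative")
    missing = set(HARVEST_TISSUES) - set(harvest["tissue"])
    if missing:
        warnings.warn(f"tissues absent, treated as zero mass: {sorted(missing)}", stacklevel=2)
    grams = harvest[value_col] * harvest["dry_mass"] / 1000.0  # mg -> g
    return grams.groupby(harvest["element"]).sum().rename("awp_g")


def dts(awp_later: float | pd.Series, awp_prev: float | pd.Series):
    """Nutrient demand between two stages (g); negative means net loss."""
    return awp_later - awp_prev


def rts(dts_interval: float | pd.Series, dts_total, signed: bool = True):
    """Interval demand as percent of the full-season (GS→DS) demand.

    ``signed=False`` uses |DTS| in both numerator and denominator for
    datasets with remobilization intervals.
    """
    total = np.asarray(dts_total, dtype=float)
    if np.any(total == 0):
        raise ValueError("full-season demand is zero; RTS undefined")
    if signed:
        return 100.0 * dts_interval / dts_total
    return 100.0 * np.abs(dts_interval) / np.abs(dts_total)


def stage_demand_table(
    harvest: pd.DataFrame,
    value_col: str = "concentration",
    signed: bool = True,
) -> pd.DataFrame:
    """Per-interval AWP / DTS / RTS table for every element.

    ``harvest`` is tidy with columns stage, tissue, element, dry_mass and
    the concentration column, averaged (or single-tree) per stage.  Fruit
    present at the maturation stage is added to the deciduous-stage totals
    before differencing, so the harvested crop counts toward full-season
    demand.  Returns a table indexed by (element, interval).
    """
    stages = [s for s in HARVEST_STAGES if s in set(harvest["stage"])]
    if len(stages) < 2:
        raise ValueError("need at least two harvest stages")
    per_stage = {s: awp(harvest[harvest["stage"] == s], value_col) for s in stages}

    if "MS" in per_stage and "DS" in per_stage:
        ms = harvest[(harvest["stage"] == "MS") & (harvest["tissue"] == "fruit")]
        if len(ms):
            fruit = (ms[value_col] * ms["dry_mass"] / 1000.0).groupby(ms["element"]).sum()
            per_stage["DS"] = per_stage["DS"].add(fruit, fill_value=0.0)

    awp_tab = pd.DataFrame(per_stage)  # elements × stages
    first, last = stages[0], stages[-1]
    rows = []
    for el in awp_tab.index:
        total = awp_tab.loc[el, last] - awp_tab.loc[el, first]
        for prev, later in zip(stages[:-1], stages[1:]):
            d = dts(awp_tab.loc[el, later], awp_tab.loc[el, prev])
            rows.append(
                {
                    "element": el,
                    "interval": f"{prev}-{later}",
                    "awp_prev": awp_tab.loc[el, prev],
                    "awp_later": awp_tab.loc[el, later],
                    "dts": d,
                    "rts": rts(d, total, signed=signed),
                }
            )
    return pd.DataFrame(rows).set_index(["element", "interval"])


class UptakeSummary(dict):
    """Per-element uptake per 1000 kg fruit with the fruit share FR."""


def uptake_per_yield(
    awp_annual: pd.Series | dict,
    yield_kg: float,
    fruit_awp: pd.Series | dict,
) -> pd.DataFrame:
    """Whole-plant and fruit nutrient uptake per 1000 kg fruit, and FR.

    ``awp_annual``/``fruit_awp`` are g per tree (full-season whole-plant
    demand and the fruit's share); ``yield_kg`` is fruit yield per tree.
    Uptake per 1000 kg fruit = (AWP g / 1000) × (1000 / yield) kg; FR is
    the fruit-to-whole-plant uptake ratio.
    """
    if yield_kg <= 0:
        raise ValueError("yield must be positive")
    total = pd.Series(awp_annual, dtype=float)
    fruit = pd.Series(fruit_awp, dtype=float).reindex(total.index)
    if (fruit > total + 1e-12).any():
        raise ValueError("fruit uptake exceeds whole-plant uptake")
    per_1000 = (total / 1000.0) * (1000.0 / yield_kg)
    fruit_1000 = (fruit / 1000.0) * (1000.0 / yield_kg)
    out = pd.DataFrame(
        {
            "total_uptake_per_1000kg": per_1000,
            "fruit_uptake_per_1000kg": fruit_1000,
            "fruit_ratio": fruit / total,
        }
    )
    out.index.name = "element"
    return out.reindex([e for e in ELEMENTS if e in out.index])
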