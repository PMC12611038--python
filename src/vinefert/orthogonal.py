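"""L16(4^5) orthogonal design: range analysis, factor F values, LSD letters.

The experiment assigns five oxide factors (N, P2O5, K2O, CaO, MgO), each at
four annual doses, to 16 treatments by the L16(4^5) orthogonal array:
every level of every factor appears in exactly four treatments, and every
ordered factor pair forms a full 4×4 Latin structure.  Because the array
is saturated (5 factors × 3 df = 15 = 16 − 1), the between-treatment sum
of squares decomposes exactly into the five factor main effects, and the
residual for F tests comes from replicate (year × rep) variation.
"""

from __future__ import annotations

import itertools
import re
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .constants import FACTORS, LEVEL_DOSES, TREATMENT_LEVELS

__all__ = [
    "DesignTable",
    "FactorAnalysis",
    "build_design",
    "dose_lookup",
    "level_means",
    "factor_f_values",
    "lsd_groups",
]

_COMBO_RE = re.compile(r"N(\d)P(\d)K(\d)Ca(\d)Mg(\d)$")


@dataclass(frozen=True)
class DesignTable:
    """Treatment → factor-level assignment with per-level annual doses."""

    levels: pd.DataFrame  # treatments × factors, level index 1..4
    doses: pd.DataFrame  # treatments × factors, kg·hm⁻²

    @property
    def treatments(self) -> list[str]:
        return list(self.levels.index)

    def validate(self) -> None:
        """Check L16(4^5) balance and pairwise orthogonality."""
        for f in FACTORS:
            counts = self.levels[f].value_counts()
            if not (counts == 4).all() or set(counts.index) != {1, 2, 3, 4}:
                raise ValueError(f"factor {f} is not balanced across treatments")
        for f1, f2 in itertools.combinations(FACTORS, 2):
            pairs = self.levels.groupby([f1, f2]).size()
            if len(pairs) != 16 or not (pairs == 1).all():
                raise ValueError(f"factors {f1},{f2} are not orthogonal")


@dataclass
class FactorAnalysis:
    """Range-analysis summary for one trait."""

    trait: str
    level_means: pd.DataFrame  # 4 levels × 5 factors
    ranges: pd.Series  # per factor, max − min of level means
    best_level: pd.Series  # per factor, argmax level (ties -> lowest)
    best_combination: str
    f_values: pd.Series | None = None
    factor_order: str | None = None


def build_design() -> DesignTable:
    """Construct the published L16(4^5) design with its annual doses."""
    lev = pd.DataFrame.from_dict(TREATMENT_LEVELS, orient="index", columns=list(FACTORS))
    lev.index.name = "treatment"
    doses = lev.apply(lambda col: [LEVEL_DOSES[col.name][v - 1] for v in col])
    design = DesignTable(levels=lev, doses=doses)
    design.validate()
    return design


def parse_combination(label: str) -> dict[str, int]:
    """Parse a label like ``"N3P1K2Ca1Mg2"`` into factor → level."""
    m = _COMBO_RE.match(label.strip())
    if not m:
        raise ValueError(f"cannot parse combination label {label!r}")
    levels = {f: int(g) for f, g in zip(FACTORS, m.groups())}
    bad = {f: v for f, v in levels.items() if not 1 <= v <= 4}
    if bad:
        raise ValueError(f"levels out of range 1..4 in {label!r}: {bad}")
    return levels


def dose_lookup(label: str, design: DesignTable | None = None) -> tuple[float, ...]:
    """Annual doses (kg·hm⁻²) for a factor-level combination label."""
    levels = parse_combination(label)
    return tuple(LEVEL_DOSES[f][levels[f] - 1] for f in FACTORS)


def _combination_label(best: pd.Series) -> str:
    tags = {"N": "N", "P2O5": "P", "K2O": "K", "CaO": "Ca", "MgO": "Mg"}
    return "".join(f"{tags[f]}{int(best[f])}" for f in FACTORS)


def _treatment_means(records: pd.DataFrame, trait: str) -> pd.Series:
    if trait not in records.columns:
        raise ValueError(f"records lack trait column {trait!r}")
    return records.groupby("treatment")[trait].mean()


def level_means(
    records: pd.DataFrame,
    design: DesignTable,
    trait: str,
    weight_by_replicates: bool = False,
) -> FactorAnalysis:
    """Range analysis of one trait over the orthogonal design.

    ``records`` is a tidy table with a ``treatment`` column and the trait
    column; by default treatment means are computed first so each
    treatment enters its level mean with equal weight (matching published
    level rows computed from treatment means).  ``weight_by_replicates``
    averages raw observations instead.
    """
    tmeans = _treatment_means(records, trait)
    missing = sorted(set(design.treatments) - set(tmeans.index))
    if missing:
        raise ValueError(f"missing treatments in records: {missing}")

    data = records if weight_by_replicates else tmeans.rename(trait).reset_index()
    merged = data.merge(design.levels, left_on="treatment", right_index=True)

    lm = pd.DataFrame(
        {f: merged.groupby(f)[trait].mean() for f in FACTORS},
        index=pd.Index([1, 2, 3, 4], name="level"),
    )
    ranges = lm.max() - lm.min()
    best = lm.idxmax()
    for f in FACTORS:
        col = lm[f]
        if (col == col.max()).sum() > 1:
            warnings.warn(f"tie in level means for {f}; lowest level chosen", stacklevel=2)
            best[f] = col[col == col.max()].index.min()
    return FactorAnalysis(
        trait=trait,
        level_means=lm,
        ranges=ranges,
        best_level=best.astype(int),
        best_combination=_combination_label(best),
    )


def order_factors(f_values: pd.Series) -> str:
    """Descending-F label string such as ``"N > P > Mg > K > Ca"``."""
    tags = {"N": "N", "P2O5": "P", "K2O": "K", "CaO": "Ca", "MgO": "Mg"}
    pos = {f: i for i, f in enumerate(FACTORS)}
    ordered = sorted(f_values.index, key=lambda f: (-f_values[f], pos[f]))
    return " > ".join(tags[f] for f in ordered)


def factor_f_values(
    records: pd.DataFrame, design: DesignTable, trait: str
) -> tuple[pd.Series, str, pd.Series]:
    """Per-factor F statistics from the saturated main-effects ANOVA.

    Factor sums of squares come from level means over all replicate
    observations; the error stratum is the within-treatment (replicate)
    residual after removing all five main effects.  Returns
    ``(f_values, factor_order, p_values)``.
    """
    tmeans = _treatment_means(records, trait)
    missing = sorted(set(design.treatments) - set(tmeans.index))
    if missing:
        raise ValueError(f"missing treatments in records: {missing}")
    counts = records.groupby("treatment")[trait].count()
    if (counts < 2).all():
        raise ValueError("F values need replicate observations (>=2 per treatment)")

    merged = records.merge(design.levels, left_on="treatment", right_index=True)
    y = merged[trait].to_numpy(dtype=float)
    grand = y.mean()
    ss_total = ((y - grand) ** 2).sum()

    ss = {}
    for f in FACTORS:
        g = merged.groupby(f)[trait]
        ss[f] = float((g.count() * (g.mean() - grand) ** 2).sum())
    ss_factors = sum(ss.values())
    ss_error = max(ss_total - ss_factors, 0.0)

    n = len(y)
    df_factor = 3
    df_error = n - 1 - df_factor * len(FACTORS)
    if df_error <= 0:
        raise ValueError("no residual degrees of freedom: add replicate observations")
    ms_error = ss_error / df_error
    if ms_error == 0:
        warnings.warn("zero residual variance; F values set to 0", stacklevel=2)
        fv = pd.Series({f: 0.0 for f in FACTORS})
    else:
        fv = pd.Series({f: (ss[f] / df_factor) / ms_error for f in FACTORS})
    fv.name = "F"
    pv = pd.Series(
        {f: float(stats.f.sf(fv[f], df_factor, df_error)) if ms_error > 0 else 1.0 for f in FACTORS},
        name="p",
    )
    return fv, order_factors(fv), pv


def lsd_groups(records: pd.DataFrame, trait: str, alpha: float = 0.05) -> pd.Series:
    """Compact letter display from pairwise least-significant-difference tests.

    Uses the pooled within-treatment mean square from a one-way ANOVA over
    treatments; two treatments differ when |mean difference| exceeds
    t(1−α/2, df_error) · sqrt(MSE·(1/n_i + 1/n_j)).  Treatments sharing a
    letter are not significantly different.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    g = records.groupby("treatment")[trait]
    means, counts = g.mean(), g.count()
    if len(means) < 2:
        raise ValueError("LSD needs at least two treatments")
    df_error = int(counts.sum() - len(means))
    sse = float(((records[trait] - records["treatment"].map(means)) ** 2).sum())
    ms_error = sse / df_error if df_error > 0 else 0.0

    order = means.sort_values(ascending=False).index
    if ms_error == 0:
        distinct = {}  # identical replicates: groups split only by exact mean
        for t in order:
            distinct.setdefault(round(means[t], 12), []).append(t)
        letters = {}
        for letter_i, (_, ts) in enumerate(distinct.items()):
            for t in ts:
                letters[t] = chr(ord("a") + letter_i)
        return pd.Series(letters, name="group").loc[means.index]

    tcrit = stats.t.ppf(1 - alpha / 2, df_error)

    def differ(a: str, b: str) -> bool:
        lsd = tcrit * np.sqrt(ms_error * (1 / counts[a] + 1 / counts[b]))
        return abs(means[a] - means[b]) > lsd

    # insert-and-absorb compact letter display over means in descending order
    groups: list[list[str]] = []
    for t in order:
        placed = False
        for grp in groups:
            if not any(differ(t, other) for other in grp):
                grp.append(t)
                placed = True
        if not placed:
            groups.append([t])
    # drop groups fully contained in another
    groups = [
        g1
        for i, g1 in enumerate(groups)
        if not any(i != j and set(g1) <= set(g2) for j, g2 in enumerate(groups))
    ]
    letters: dict[str, str] = {}
    for letter_i, grp in enumerate(groups):
        for t in grp:
            letters[t] = letters.get(t, "") + chr(ord("a") + letter_i)
    return pd.Series(letters, name="group").loc[means.index]
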