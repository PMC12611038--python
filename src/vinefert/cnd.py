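"""Compositional-nutrient-diagnosis cutoff machinery.

Given one nutrient variable (a stage × tissue or stage soil concentration)
measured on n experimental units together with a normalized fruit quality
index in [0, 1], the units are sorted by quality (descending) and every
admissible split into a candidate high-quality head group and a low-quality
tail is scored by the variance ratio V_j = Var(top j) / Var(rest).  The
running sum of the V_j, normalized to end at 100, defines the cumulative
variance-ratio function F(X) of the quality score X at each split.  A cubic
A·X³ + B·X² + C·X + D is fitted by ordinary least squares and its inflection
point Y = −B/(3A) is the diagnostic cutoff: units with fqi_norm ≥ Y form the
high-quality reference sub-population, and the min–max interval of the
nutrient over that sub-population is its optimum (sufficiency) range.

Sample statistics use the n−1 denominator throughout.  Ties in fqi_norm are
kept together: splits only occur where the sorted score strictly decreases.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CutoffFit",
    "OptimumRange",
    "select_diagnostic_tissue",
    "cumulative_variance_function",
    "fit_cubic",
    "inflection_cutoff",
    "select_high_subpop",
    "optimum_range",
    "communal_cutoff",
    "correlation_matrix",
    "diagnose_variable",
]


@dataclass
class CutoffFit:
    """Cubic cumulative-variance fit for one diagnostic variable."""

    variable: str
    A: float
    B: float
    C: float
    D: float
    r_squared: float
    cutoff: float | None
    n_points: int

    @property
    def coefficients(self) -> tuple[float, float, float, float]:
        return (self.A, self.B, self.C, self.D)


@dataclass
class OptimumRange:
    """Sufficiency window of a nutrient over the high-FQI sub-population."""

    variable: str
    low: float
    high: float
    cutoff_used: float
    subpop_size: int
    subpop_fraction: float  # percent of all units


def select_diagnostic_tissue(
    plant: pd.DataFrame,
    value_col: str = "value",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pick, per element, the stage × tissue with the lowest coefficient of variation.

    ``plant`` is tidy with columns stage, tissue, element and the value
    column.  Returns ``(choice, cv_table)`` where ``choice`` has one row
    per element (stage, tissue, cv_pct) and ``cv_table`` lists the CV
    (100·SD/mean, sample SD) of every stage × tissue × element variable.
    Variables with non-positive mean are excluded with a warning.
    """
    required = {"stage", "tissue", "element", value_col}
    if not required <= set(plant.columns):
        raise ValueError(f"plant table needs columns {sorted(required)}")
    g = plant.groupby(["element", "stage", "tissue"])[value_col]
    summary = g.agg(["mean", "std", "count"])
    if (summary["count"] < 2).any():
        raise ValueError("need >=2 observations per stage × tissue × element")
    bad = summary[summary["mean"] <= 0]
    if len(bad):
        warnings.warn(
            f"excluding {len(bad)} variables with non-positive mean", stacklevel=2
        )
        summary = summary[summary["mean"] > 0]
    cv = (100.0 * summary["std"] / summary["mean"]).rename("cv_pct").reset_index()
    choice = (
        cv.sort_values(["element", "cv_pct", "stage", "tissue"], kind="stable")
        .groupby("element", sort=False)
        .head(1)
        .set_index("element")
    )
    return choice, cv


def _split_points(fqi_norm: np.ndarray, m_min: int) -> tuple[np.ndarray, list[int]]:
    """Sorted scores (descending) and admissible head sizes, keeping ties together."""
    order = np.argsort(-fqi_norm, kind="stable")
    s = fqi_norm[order]
    n = len(s)
    splits = [
        j
        for j in range(m_min, n - m_min + 1)
        if s[j - 1] > s[j]  # only split where the score strictly drops
    ]
    return order, splits


def cumulative_variance_function(
    values: np.ndarray | pd.Series,
    fqi_norm: np.ndarray | pd.Series,
    m_min: int = 3,
    orientation: str = "top_over_rest",
) -> pd.DataFrame:
    """Cumulative variance-ratio curve (X_j, F_j) over all admissible splits.

    Units are sorted by fqi_norm descending; for each admissible head size
    j, V_j = Var(top j)/Var(rest) (or the reciprocal under
    ``orientation="rest_over_top"``) and F_j = 100·Σ_{i≤j} V_i / Σ V_i.
    X_j is the fqi_norm of the j-th sorted unit.  F is non-decreasing in j
    (hence non-increasing in X) and ends at exactly 100.
    """
    v = np.asarray(values, dtype=float)
    x = np.asarray(fqi_norm, dtype=float)
    if v.shape != x.shape or v.ndim != 1:
        raise ValueError("values and fqi_norm must be 1-d of equal length")
    n = len(v)
    if m_min < 2:
        raise ValueError("m_min must be >= 2 so both subgroup variances exist")
    if n < 2 * m_min + 1:
        raise ValueError(f"need at least {2 * m_min + 1} units, got {n}")
    if np.ptp(x) == 0:
        raise ValueError("fqi_norm values are all equal; no splits possible")
    if orientation not in ("top_over_rest", "rest_over_top"):
        raise ValueError(f"unknown orientation {orientation!r}")

    order, splits = _split_points(x, m_min)
    vs, xs = v[order], x[order]

    ratios, xpts, kept = [], [], []
    for j in splits:
        var_top = vs[:j].var(ddof=1)
        var_rest = vs[j:].var(ddof=1)
        num, den = (var_top, var_rest) if orientation == "top_over_rest" else (var_rest, var_top)
        if den == 0:
            warnings.warn(f"zero variance at split j={j}; skipped", stacklevel=2)
            continue
        ratios.append(num / den)
        xpts.append(xs[j - 1])
        kept.append(j)
    if not ratios:
        raise ValueError("all splits had a zero-variance subgroup")
    ratios = np.asarray(ratios)
    F = 100.0 * np.cumsum(ratios) / ratios.sum()
    return pd.DataFrame({"j": kept, "X": xpts, "V": ratios, "F": F})


def fit_cubic(points: pd.DataFrame, variable: str = "") -> CutoffFit:
    """Ordinary least-squares cubic F = A·X³ + B·X² + C·X + D through the curve.

    ``points`` needs columns X and F (as from
    :func:`cumulative_variance_function`).  The cutoff field holds the
    inflection −B/(3A), or None (with a warning) when the cubic term is
    numerically zero.
    """
    X = np.asarray(points["X"], dtype=float)
    F = np.asarray(points["F"], dtype=float)
    if len(np.unique(X)) < 4:
        raise ValueError("cubic fit needs at least 4 distinct X values")
    coeffs = np.polyfit(X, F, 3)
    A, B, C, D = (float(c) for c in coeffs)
    resid = F - np.polyval(coeffs, X)
    ss_tot = float(((F - F.mean()) ** 2).sum())
    r2 = 1.0 - float((resid**2).sum()) / ss_tot if ss_tot > 0 else 1.0
    scale = max(abs(B), abs(C), abs(D), 1.0)
    if abs(A) <= 1e-10 * scale:
        warnings.warn(f"cubic term ~0 for {variable or 'variable'}; cutoff undefined", stacklevel=2)
        cutoff = None
    else:
        cutoff = inflection_cutoff(A, B)
    return CutoffFit(
        variable=variable, A=A, B=B, C=C, D=D, r_squared=r2, cutoff=cutoff, n_points=len(X)
    )


def inflection_cutoff(A: float, B: float) -> float:
    """Inflection point Y = −B/(3A) of the cubic (zero of 6A·X + 2B)."""
    if A == 0:
        raise ValueError("cutoff undefined: cubic coefficient A is zero")
    return -B / (3.0 * A)


def select_high_subpop(fqi_norm: pd.Series, cutoff: float) -> tuple[pd.Series, float]:
    """Units with fqi_norm ≥ cutoff and their percentage of the cohort."""
    if not np.isfinite(cutoff):
        raise ValueError("cutoff must be finite")
    s = pd.Series(fqi_norm, dtype=float)
    sel = s[s >= cutoff]
    if sel.empty:
        raise ValueError(
            f"no units at or above cutoff {cutoff:.4f} (max fqi_norm {s.max():.4f}); "
            "review the cutoff"
        )
    return sel, 100.0 * len(sel) / len(s)


def optimum_range(
    values: pd.Series | np.ndarray,
    variable: str = "",
    cutoff_used: float = float("nan"),
    n_total: int | None = None,
) -> OptimumRange:
    """Min–max sufficiency window of a nutrient over the reference sub-population."""
    v = np.asarray(values, dtype=float)
    if len(v) < 2:
        raise ValueError("optimum range needs a sub-population of >=2 units")
    frac = 100.0 * len(v) / n_total if n_total else float("nan")
    return OptimumRange(
        variable=variable,
        low=float(v.min()),
        high=float(v.max()),
        cutoff_used=cutoff_used,
        subpop_size=len(v),
        subpop_fraction=frac,
    )


def communal_cutoff(fits: list[CutoffFit]) -> float:
    """Communal cutoff across plant diagnostic variables: the maximum defined cutoff.

    The most stringent (highest) plant cutoff defines the communal
    high-quality reference sub-population used for the cross-variable
    optimum ranges.
    """
    cutoffs = [f.cutoff for f in fits if f.cutoff is not None]
    if not cutoffs:
        raise ValueError("no defined cutoffs among the fits")
    return max(cutoffs)


def diagnose_variable(
    values: pd.Series,
    fqi_norm: pd.Series,
    variable: str = "",
    m_min: int = 3,
    cutoff: float | None = None,
) -> tuple[CutoffFit, OptimumRange]:
    """Full single-variable diagnosis: curve → cubic → cutoff → optimum range.

    ``cutoff`` overrides the fitted inflection (used for communal-cutoff
    ranges).  Values and fqi_norm must share an index.
    """
    values = pd.Series(values, dtype=float)
    fqi_norm = pd.Series(fqi_norm, dtype=float)
    points = cumulative_variance_function(values.to_numpy(), fqi_norm.to_numpy(), m_min=m_min)
    fit = fit_cubic(points, variable=variable)
    use = cutoff if cutoff is not None else fit.cutoff
    if use is None:
        raise ValueError(f"no usable cutoff for {variable or 'variable'}")
    sel, frac = select_high_subpop(fqi_norm, use)
    rng = optimum_range(
        values.loc[sel.index], variable=variable, cutoff_used=use, n_total=len(values)
    )
    return fit, rng


def correlation_matrix(
    left: pd.DataFrame, right: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Pairwise Pearson correlations with two-sided p-values and stars.

    Correlates every column of ``left`` with every column of ``right``
    (or all column pairs of ``left`` when ``right`` is None), aligning on
    the index.  Zero-variance series are skipped with a warning.  Stars:
    ``*`` p<0.05, ``**`` p<0.01, ``***`` p<0.001.
    """
    if right is None:
        right = left
    rows = []
    for a in left.columns:
        for b in right.columns:
            x, y = left[a].align(right[b], join="inner")
            mask = x.notna() & y.notna()
            x, y = x[mask], y[mask]
            if len(x) < 3:
                raise ValueError(f"pair ({a}, {b}) has fewer than 3 paired observations")
            if x.std(ddof=1) == 0 or y.std(ddof=1) == 0:
                warnings.warn(f"zero variance in pair ({a}, {b}); skipped", stacklevel=2)
                continue
            r, p = stats.pearsonr(x, y)
            stars = "***" if p < 0.001 else "**" if p < 0.01 else "*" if p < 0.05 else ""
            rows.append({"x": a, "y": b, "r": float(r), "p": float(p), "sig": stars, "n": len(x)})
    return pd.DataFrame(rows)
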