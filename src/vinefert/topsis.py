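"""Fruit quality index by TOPSIS.

The fruit quality index (FQI) is the TOPSIS closeness coefficient over
single fruit weight (SFW, g), total soluble solids (TSS, %) and fruit
firmness (FF, g puncture force), with fixed exogenous weights
(0.0470, 0.2089, 0.1778).  Each criterion column is vector-normalized
(divided by its Euclidean norm), weighted, and every alternative is scored
by its closeness D⁻/(D⁺+D⁻) to the ideal / anti-ideal profile.  The
closeness coefficient is invariant to a common rescaling of the weights,
so the weights are used exactly as printed (their sum, 0.4337, is not
forced to 1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constants import QUALITY_TRAITS, QUALITY_WEIGHTS

__all__ = [
    "TopsisConfig",
    "FqiResult",
    "topsis_score",
    "normalize_fqi",
    "percent_change",
    "fqi_table",
]


@dataclass
class TopsisConfig:
    """Weights, criterion directions and normalization scheme for TOPSIS.

    ``directions`` entries are ``"benefit"`` (higher is better) or
    ``"cost"``; all three quality traits are benefit criteria by default.
    ``normalization`` is ``"vector"`` (classical TOPSIS) or ``"minmax"``.
    """

    weights: tuple[float, ...] = tuple(QUALITY_WEIGHTS[t] for t in QUALITY_TRAITS)
    directions: tuple[str, ...] = ("benefit",) * 3
    normalization: str = "vector"

    def __post_init__(self) -> None:
        if any(w < 0 for w in self.weights):
            raise ValueError("weights must be non-negative")
        if len(self.weights) != len(self.directions):
            raise ValueError("weights and directions must have equal length")
        bad = set(self.directions) - {"benefit", "cost"}
        if bad:
            raise ValueError(f"unknown criterion directions: {sorted(bad)}")
        if self.normalization not in ("vector", "minmax"):
            raise ValueError(f"unknown normalization {self.normalization!r}")


@dataclass
class FqiResult:
    """TOPSIS scores for one cohort of alternatives."""

    fqi: pd.Series
    d_plus: pd.Series
    d_minus: pd.Series
    rank: pd.Series = field(init=False)

    def __post_init__(self) -> None:
        self.rank = self.fqi.rank(ascending=False, method="min").astype(int)

    @property
    def fqi_norm(self) -> pd.Series:
        return normalize_fqi(self.fqi)


def topsis_score(matrix: pd.DataFrame | np.ndarray, config: TopsisConfig | None = None) -> FqiResult:
    """Score alternatives (rows) against criteria (columns) by TOPSIS.

    Parameters
    ----------
    matrix:
        Alternatives × criteria decision matrix; all entries must be finite
        and positive.
    config:
        Weights/directions/normalization; defaults to the packaged
        SFW/TSS/FF configuration.

    Returns
    -------
    FqiResult with the closeness coefficient (``fqi``), the distances to
    the ideal (``d_plus``) and anti-ideal (``d_minus``) profiles, and ranks.
    """
    if config is None:
        config = TopsisConfig()
    X = pd.DataFrame(matrix).astype(float)
    if X.shape[0] < 2:
        raise ValueError("TOPSIS needs at least two alternatives")
    if X.shape[1] != len(config.weights):
        raise ValueError(
            f"matrix has {X.shape[1]} criteria but config has {len(config.weights)} weights"
        )
    if not np.isfinite(X.to_numpy()).all():
        raise ValueError("criteria values must be finite")
    if (X.to_numpy() <= 0).any():
        raise ValueError("criteria values must be positive")

    V = X.to_numpy()
    if config.normalization == "vector":
        norms = np.sqrt((V**2).sum(axis=0))
        if (norms == 0).any():
            raise ValueError("all-zero criterion column")
        R = V / norms
    else:  # minmax
        lo, hi = V.min(axis=0), V.max(axis=0)
        span = np.where(hi > lo, hi - lo, 1.0)
        R = (V - lo) / span

    W = R * np.asarray(config.weights)
    benefit = np.array([d == "benefit" for d in config.directions])
    ideal = np.where(benefit, W.max(axis=0), W.min(axis=0))
    anti = np.where(benefit, W.min(axis=0), W.max(axis=0))

    d_plus = np.sqrt(((W - ideal) ** 2).sum(axis=1))
    d_minus = np.sqrt(((W - anti) ** 2).sum(axis=1))
    denom = d_plus + d_minus
    fqi = np.empty_like(denom)
    degenerate = denom == 0
    if degenerate.any():
        warnings.warn(
            "alternatives identical on all criteria; closeness set to 0.5",
            stacklevel=2,
        )
    fqi[degenerate] = 0.5
    fqi[~degenerate] = d_minus[~degenerate] / denom[~degenerate]

    idx = X.index
    return FqiResult(
        fqi=pd.Series(fqi, index=idx, name="fqi"),
        d_plus=pd.Series(d_plus, index=idx, name="d_plus"),
        d_minus=pd.Series(d_minus, index=idx, name="d_minus"),
    )


def normalize_fqi(fqi: pd.Series | np.ndarray) -> pd.Series:
    """Min–max rescale a score vector to [0, 1] within its cohort."""
    s = pd.Series(fqi, dtype=float)
    lo, hi = s.min(), s.max()
    if len(s) < 2 or hi == lo:
        raise ValueError("min–max normalization undefined: need >=2 distinct values")
    out = (s - lo) / (hi - lo)
    out.name = "fqi_norm"
    return out


def percent_change(value: float, reference: float) -> float:
    """Relative change of ``value`` against ``reference``, in percent."""
    if reference <= 0:
        raise ValueError("reference must be positive")
    return 100.0 * (value / reference - 1.0)


def fqi_table(
    quality: pd.DataFrame,
    config: TopsisConfig | None = None,
    cohort: str | list[str] | None = None,
    traits: tuple[str, ...] = QUALITY_TRAITS,
) -> pd.DataFrame:
    """Attach fqi / fqi_norm / rank columns to a tidy quality table.

    ``cohort`` optionally names grouping columns (e.g. ``"year"``); TOPSIS
    and the min–max normalization are then computed within each cohort.
    The default scores all rows as one pooled cohort.
    """
    missing = [t for t in traits if t not in quality.columns]
    if missing:
        raise ValueError(f"quality table missing trait columns: {missing}")
    out = quality.copy()

    def _score(df: pd.DataFrame) -> pd.DataFrame:
        res = topsis_score(df[list(traits)], config)
        df = df.copy()
        df["fqi"] = res.fqi
        df["fqi_norm"] = res.fqi_norm
        df["rank"] = res.rank
        return df

    if cohort is None:
        return _score(out)
    keys = [cohort] if isinstance(cohort, str) else list(cohort)
    pieces = [_score(g) for _, g in out.groupby(keys, sort=False)]
    return pd.concat(pieces).loc[out.index]
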