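"""Soil-test-driven precision fertilization model.

For each growth interval and oxide nutrient, a linear soil-test response
y = a·x + b (a < 0: richer soil needs less fertilizer) converts the
measured soil concentration x (mg·g⁻¹) at the interval's start stage into
a base dose calibrated to a 1500 kg yield unit.  The recommended precision
fertilization amount scales the base dose by expected yield through the
fruit uptake share FR:

    PFA = (1 − FR)·(a·x + b) + FR·(EY/1500)·(a·x + b)   if x < X_max
    PFA = 0                                              if x ≥ X_max

where X_max is the upper bound of the nutrient's optimum (sufficiency)
range for the start-stage soil variable.  At each successive stage the
soil is re-tested and the gate re-applied, so fertilization stops for any
nutrient whose soil supply has reached sufficiency.  Negative base doses
(very rich soils still below X_max) are floored at zero with a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from . import constants
from .constants import FACTORS, INTERVALS

__all__ = [
    "StageModel",
    "FertilizerCatalog",
    "default_stage_models",
    "pfa",
    "annual_plan",
    "split_by_demand_ratio",
    "solve_blend",
    "oxide_to_element",
    "element_to_oxide",
]


@dataclass(frozen=True)
class StageModel:
    """Linear soil-test response for one interval × oxide."""

    interval: str
    oxide: str
    a: float  # kg per (mg·g⁻¹) of soil test, negative
    b: float  # kg at zero soil test
    x_max: float  # mg·g⁻¹ sufficiency bound

    def __post_init__(self) -> None:
        if self.x_max <= 0:
            raise ValueError("x_max must be positive")


def default_stage_models() -> dict[tuple[str, str], StageModel]:
    """The 25 packaged interval × oxide models with their X_max gates."""
    tab = constants.stage_models()
    return {
        (i, o): StageModel(interval=i, oxide=o, a=row["a"], b=row["b"], x_max=row["x_max"])
        for (i, o), row in tab.iterrows()
    }


def pfa(x: float, model: StageModel, fr: float, ey: float) -> float:
    """Precision fertilization amount (kg) for one soil test.

    ``x`` is the soil concentration (mg·g⁻¹) at the interval's start
    stage, ``fr`` the fruit-to-whole-plant uptake ratio in [0, 1], ``ey``
    the expected yield (kg) against the 1500 kg calibration unit.
    """
    if x < 0:
        raise ValueError("soil test must be non-negative")
    if not 0 <= fr <= 1:
        raise ValueError("FR must be in [0, 1]")
    if ey <= 0:
        raise ValueError("expected yield must be positive")
    if x >= model.x_max:
        return 0.0
    base = model.a * x + model.b
    amount = base * ((1.0 - fr) + fr * ey / 1500.0)
    if amount < 0:
        warnings.warn(
            f"negative dose for {model.interval} {model.oxide} at x={x}; floored at 0",
            stacklevel=2,
        )
        return 0.0
    return float(amount)


def annual_plan(
    soil_tests: pd.DataFrame,
    models: dict[tuple[str, str], StageModel] | None = None,
    fruit_ratios: dict[str, float] | None = None,
    ey: float = 1500.0,
) -> pd.DataFrame:
    """Stage-by-stage fertilization plan from per-stage soil tests.

    ``soil_tests`` is indexed by interval (or start stage) with one oxide
    column per factor (mg·g⁻¹, element measurements mapped to their
    oxide's column).  Each interval is evaluated independently in
    phenological order, re-applying the sufficiency gate at every stage.
    Returns a table indexed by (interval, oxide) with the soil test, gate
    state and recommended amount, plus per-oxide annual totals.
    """
    if models is None:
        models = default_stage_models()
    if fruit_ratios is None:
        fruit_ratios = dict(constants.FRUIT_RATIOS)

    tests = soil_tests.copy()
    stage_to_interval = {iv.split("-")[0]: iv for iv in INTERVALS}
    tests.index = [stage_to_interval.get(str(i), str(i)) for i in tests.index]

    rows = []
    for interval in INTERVALS:
        if interval not in tests.index:
            raise ValueError(f"missing soil tests for interval {interval}")
        for oxide in FACTORS:
            if (interval, oxide) not in models:
                raise ValueError(f"missing stage model for ({interval}, {oxide})")
            if oxide not in tests.columns:
                raise ValueError(f"soil tests lack column {oxide}")
            model = models[(interval, oxide)]
            x = float(tests.loc[interval, oxide])
            amount = pfa(x, model, fruit_ratios[oxide], ey)
            rows.append(
                {
                    "interval": interval,
                    "oxide": oxide,
                    "soil_test": x,
                    "x_max": model.x_max,
                    "sufficient": x >= model.x_max,
                    "pfa_kg": amount,
                }
            )
    plan = pd.DataFrame(rows).set_index(["interval", "oxide"])
    plan.attrs["annual_totals"] = plan["pfa_kg"].groupby(level="oxide").sum().to_dict()
    plan.attrs["ey"] = ey
    return plan


def split_by_demand_ratio(
    annual_dose: float, ratios: tuple[float, ...] | list[float]
) -> tuple[float, ...]:
    """Split an annual dose over the five intervals proportionally to ratios."""
    r = np.asarray(ratios, dtype=float)
    if (r < 0).any():
        raise ValueError("ratios must be non-negative")
    total = r.sum()
    if total == 0:
        raise ValueError("ratios must not all be zero")
    return tuple(float(annual_dose * ri / total) for ri in r)


@dataclass
class FertilizerCatalog:
    """Physical fertilizer products and their oxide nutrient fractions."""

    products: dict[str, dict[str, float]]

    def __post_init__(self) -> None:
        if not self.products:
            raise ValueError("catalog is empty")
        for name, fracs in self.products.items():
            if not fracs:
                raise ValueError(f"product {name!r} declares no nutrients")
            for oxide, f in fracs.items():
                if not 0 < f <= 1:
                    raise ValueError(f"fraction {f} of {oxide} in {name!r} not in (0, 1]")
            if sum(fracs.values()) > 1 + 1e-9:
                raise ValueError(f"fractions of {name!r} exceed 1")

    @classmethod
    def default(cls) -> "FertilizerCatalog":
        return cls(products={k: dict(v) for k, v in constants.FERTILIZER_CATALOG.items()})

    def matrix(self, oxides: tuple[str, ...] = FACTORS) -> pd.DataFrame:
        """Oxides × products delivery matrix (kg nutrient per kg product)."""
        return pd.DataFrame(
            {name: [fracs.get(o, 0.0) for o in oxides] for name, fracs in self.products.items()},
            index=list(oxides),
        )


def solve_blend(
    targets: dict[str, float] | pd.Series,
    catalog: FertilizerCatalog | None = None,
) -> pd.DataFrame:
    """Non-negative least-squares blend of physical fertilizers.

    Finds product masses ≥ 0 minimizing the squared deviation of delivered
    oxide nutrients from the targets (kg).  Returns a product table with
    the solved masses plus an ``attrs['delivered']`` / ``attrs['residual']``
    per-oxide account; residuals are reported, never hidden.
    """
    if catalog is None:
        catalog = FertilizerCatalog.default()
    t = pd.Series(targets, dtype=float)
    if (t < 0).any():
        raise ValueError("targets must be non-negative")
    oxides = tuple(t.index)
    A = catalog.matrix(oxides)
    masses, _ = nnls(A.to_numpy(), t.to_numpy())
    masses = pd.Series(masses, index=A.columns, name="product_kg")
    delivered = A @ masses
    out = masses.to_frame()
    out.attrs["delivered"] = delivered.to_dict()
    out.attrs["residual"] = (delivered - t).to_dict()
    return out


def oxide_to_element(oxide: str, amount: float) -> float:
    """Convert an oxide mass to its element mass (P2O5 → P etc.)."""
    return amount * constants.OXIDE_TO_ELEMENT[oxide]


def element_to_oxide(oxide: str, amount: float) -> float:
    """Convert an element mass to the oxide basis used by the design tables."""
    return amount / constants.OXIDE_TO_ELEMENT[oxide]
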