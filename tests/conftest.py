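import numpy as np
import pandas as pd
import pytest

from vinefert import constants
from vinefert.orthogonal import build_design


@pytest.fixture(scope="session")
def design():
    return build_design()


@pytest.fixture(scope="session")
def treatment_means():
    """Published five-year treatment means as a tidy table."""
    return constants.treatment_means().reset_index()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_quality(values: dict[str, float], n_reps: int = 3, noise: float = 0.0,
                 rng: np.random.Generator | None = None, trait: str = "y") -> pd.DataFrame:
    """Tiny replicate-level quality table from per-treatment means."""
    rng = rng or np.random.default_rng(0)
    rows = []
    for t, mean in values.items():
        for r in range(n_reps):
            rows.append({"treatment": t, "rep": r + 1,
                         trait: mean + (rng.normal(0, noise) if noise else 0.0)})
    return pd.DataFrame(rows)
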