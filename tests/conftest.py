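import numpy as np
import pandas as pd
import pytest

from skewfit import CohortConfig, cohort_to_frame, generate_cohort


@pytest.fixture(scope="session")
def cohort_frame() -> pd.DataFrame:
    """Default synthetic cohort (n=883, seed=1), shared across tests."""
    return cohort_to_frame(generate_cohort(CohortConfig(seed=1)))


@pytest.fixture(scope="session")
def small_frame() -> pd.DataFrame:
    """A small cohort for cheap structural tests."""
    return cohort_to_frame(generate_cohort(CohortConfig(n=250, seed=7)))


def frame_from_values(y, name="vcat") -> pd.DataFrame:
    """Minimal cohort frame wrapping a raw outcome vector."""
    y = np.asarray(y)
    n = y.size
    return pd.DataFrame({
        "id": np.arange(1, n + 1),
        "age": np.full(n, 60.0),
        "sex": ["male"] * n,
        "education": np.full(n, 10.0),
        name: y,
    })
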