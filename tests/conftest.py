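import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from vfprog.errors import default_error_table
from vfprog.model import make_grid
from vfprog.simulate import CohortConfig, NoiseModel, generate_cohort

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def grid():
    return make_grid()


@pytest.fixture(scope="session")
def table():
    return default_error_table()


@pytest.fixture(scope="session")
def stable_cohort_small():
    """Ten stable 7-visit series with default skewed noise."""
    return generate_cohort(CohortConfig(n_eyes=10, n_visits=7, seed=11))


@pytest.fixture(scope="session")
def noiseless_series():
    """One noise-free stable series (every visit equals baseline exactly)."""
    cfg = CohortConfig(n_eyes=1, n_visits=7, noise=NoiseModel(sd_scale=0.0), seed=5)
    return generate_cohort(cfg)[0]
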