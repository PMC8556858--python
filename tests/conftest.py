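import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import opsmodel as om

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.filter_too_much],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def profile():
    """Standard synthetic ring profile used throughout the suite."""
    return om.default_ring_profile(seed=1)


@pytest.fixture(scope="session")
def baseline():
    return om.ModelParameters()


@pytest.fixture(scope="session")
def small_params():
    """Scaled-down population for fast unit tests."""
    return om.ModelParameters(n_users_initial=2000, horizon_days=30, new_entrants_per_day=1.0)


@pytest.fixture(scope="session")
def single_ring_profile():
    return om.RingProfile(
        lo=np.array([0.0]),
        hi=np.array([np.inf]),
        visit_scale=np.array([1.0]),
        population_proportion=np.array([1.0]),
        base_visit_prob=1.0,
    )
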