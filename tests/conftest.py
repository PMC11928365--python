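import numpy as np
import pytest

from tsce.core import RateSchedule, schedule_from_params
from tsce.params import REFERENCE_PARAMS


@pytest.fixture(scope="session")
def nhb_male():
    return REFERENCE_PARAMS[("NHB", "male")]


@pytest.fixture(scope="session")
def nhw_male():
    return REFERENCE_PARAMS[("NHW", "male")]


@pytest.fixture(scope="session")
def background_schedule(nhb_male):
    """Never-smoker (constant background) schedule."""
    return schedule_from_params(nhb_male, [0.0], [0.0])


@pytest.fixture(scope="session")
def smoker_schedule(nhb_male):
    """20 cigarettes/day from age 20, never quit."""
    return schedule_from_params(nhb_male, [0.0, 20.0], [0.0, 20.0])


def random_schedule(rng):
    """A random valid schedule spanning realistic cohort magnitudes."""
    K = int(rng.integers(1, 5))
    edges = np.concatenate([[0.0], np.sort(rng.uniform(1.0, 90.0, K - 1))])
    mu1 = 10.0 ** rng.uniform(-8, -5, K)
    g = rng.uniform(0.01, 0.25, K)
    alpha = np.full(K, 3.0)
    nu = 10.0 ** rng.uniform(-1, 1.2, K)
    return RateSchedule(edges, nu, alpha, alpha - g - mu1, mu1)


@pytest.fixture(scope="session")
def small_cohort():
    """A 3,000-person single-group cohort shared across fast tests."""
    from tsce.synthetic import generate_cohort, single_group_config

    return generate_cohort(single_group_config("NHB", "male", 3000, seed=7))
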