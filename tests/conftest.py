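import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import qreport as q

settings.register_profile(
    "deterministic", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def region_map():
    return q.default_region_map()


@pytest.fixture(scope="session")
def normative_cohort():
    return q.simulate_normative_population(seed=11)


@pytest.fixture(scope="session")
def model(normative_cohort):
    return q.fit_normative_model(normative_cohort, cdf_variant="gaussian")


@pytest.fixture(scope="session")
def test_cohort():
    return q.simulate_test_cohort(seed=13)


@pytest.fixture(scope="session")
def sim_study():
    """One complete simulated nine-rater study: (cohort, gold, ratings)."""
    return q.simulate_study(seed=17)


@pytest.fixture()
def rng():
    return np.random.default_rng(2026)
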