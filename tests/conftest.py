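import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import hrvtbi as h

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")

#: Short phase durations used where a full 22-minute baseline is unnecessary.
FAST_COHORT = h.CohortConfig(
    baseline_duration=180.0, hemorrhage_duration=120.0, post_duration=120.0
)


@pytest.fixture(scope="session")
def default_cohort():
    """One full-duration cohort at the default study conditions."""
    return h.generate_cohort(seed=7)


@pytest.fixture(scope="session")
def default_features(default_cohort):
    series = [rr for s in default_cohort for rr in s.phases.values()]
    return h.cohort_feature_table(series)


@pytest.fixture(scope="session")
def fast_cohort():
    return h.generate_cohort(FAST_COHORT, seed=11)


@pytest.fixture(scope="session")
def fast_features(fast_cohort):
    series = [rr for s in fast_cohort for rr in s.phases.values()]
    return h.cohort_feature_table(series)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
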