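import pytest
from hypothesis import HealthCheck, settings

from pps import cvd_risk, lesion_scoring, synthetic_cohort

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def scheme():
    return lesion_scoring.default_scheme()


@pytest.fixture(scope="session")
def rules():
    return cvd_risk.default_rules()


@pytest.fixture(scope="session")
def small_cohort():
    """The hand-set 12-participant cohort used across module tests."""
    return synthetic_cohort.fixture_small()
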