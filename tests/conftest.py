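import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from orcurve import AnalyticSample, nhanes_like_fixture

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=100,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def toy_sample() -> AnalyticSample:
    """Eight records, both outcomes on both sides of mid-range cutoffs."""
    return AnalyticSample(
        exposure=np.array([20.0, 22.0, 24.0, 25.0, 26.0, 28.0, 30.0, 35.0]),
        case=np.array([0, 1, 0, 1, 1, 0, 1, 1]),
    )


@pytest.fixture(scope="session")
def fixture_sample() -> AnalyticSample:
    """The standard right-skewed large-sample fixture (seeded)."""
    return nhanes_like_fixture(seed=1)


@pytest.fixture(scope="session")
def small_fixture_sample() -> AnalyticSample:
    """Reduced-n version for cheaper whole-curve assertions."""
    return nhanes_like_fixture(seed=2, n=4000)
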