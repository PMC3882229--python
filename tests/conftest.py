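import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from cboost import SurvivalSample

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=40,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20240)


@pytest.fixture
def censored_sample(rng):
    """A moderately censored sample with 3 markers, tie-free times."""
    n = 40
    t = rng.exponential(2.0, n) + 1e-3
    e = rng.integers(0, 2, n).astype(float)
    e[np.argmin(t)] = 1  # guarantee a usable pair
    return SurvivalSample(t, e, rng.normal(size=(n, 3)))


@pytest.fixture
def uncensored_sample(rng):
    n = 30
    t = rng.exponential(1.0, n) + 1e-3
    return SurvivalSample(t, np.ones(n), rng.normal(size=(n, 2)))
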