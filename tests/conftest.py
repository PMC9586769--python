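import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from hawkespd import MonitoredSeries, TRUE_PARAMS
from hawkespd.simulate import study_config, simulate_series

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def truth():
    return TRUE_PARAMS


@pytest.fixture(scope="session")
def noiseless_study():
    """One noiseless study draw: (noisy==clean series, config)."""
    sim = study_config(seed=11, noise_variance=0.0)
    noisy, clean = simulate_series(sim)
    return noisy, sim


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def random_series(rng):
    return MonitoredSeries(rng.normal(size=128))
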