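import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "det",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("det")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def clean_dataset():
    """A deterministic noise-free synthetic dataset shared across tests."""
    from aquahichip import SimulationConfig
    from aquahichip.simulate import simulate_dataset

    return simulate_dataset(SimulationConfig(seed=1, noise=False))
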