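import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

import gazeload as gz


@pytest.fixture(scope="session")
def default_config() -> gz.GeneratorConfig:
    return gz.GeneratorConfig()


@pytest.fixture(scope="session")
def noise_free_config() -> gz.GeneratorConfig:
    return gz.GeneratorConfig.noise_free()


@pytest.fixture(scope="session")
def sim_trial(default_config):
    """One noisy peak-condition trial with ground truth (seeded)."""
    return gz.simulate_trial(default_config, "EN-Familiar", "P01", 11)


@pytest.fixture(scope="session")
def sim_session(default_config):
    """One full four-condition session with ground truth (seeded)."""
    return gz.simulate_session(default_config, "P01", 7)


def uniform_times(n: int, rate_hz: float = 90.0) -> np.ndarray:
    return np.arange(n) / rate_hz
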