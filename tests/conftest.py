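import numpy as np
import pytest

from mutacc.simgen import SimulationConfig, generate_reference


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    return SimulationConfig(genome_length=100_000, seed=7)


@pytest.fixture(scope="session")
def small_reference(small_config):
    """100 kb synthetic reference shared across read-only tests."""
    return generate_reference(small_config)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
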