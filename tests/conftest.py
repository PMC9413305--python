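import numpy as np
import pytest

from kicktrack import KickProfile, NoiseModel, PipelineConfig, simulate_kick
from kicktrack.simulator import synthetic_kick_experiment


@pytest.fixture()
def config() -> PipelineConfig:
    return PipelineConfig()


@pytest.fixture(scope="session")
def default_kick():
    """One simulated kick under the default (randomized) sensor model."""
    profile = KickProfile()
    noise = NoiseModel.randomized(3)
    truth, sim = simulate_kick(profile, noise)
    return profile, noise, truth, sim


@pytest.fixture(scope="session")
def noiseless_kick():
    """One simulated kick from a perfect, unquantized sensor."""
    profile = KickProfile()
    truth, sim = simulate_kick(profile, NoiseModel.noiseless())
    return profile, truth, sim


@pytest.fixture(scope="session")
def ten_seed_runs():
    """Closed-loop experiments for seeds 1..10 under the default profile."""
    return [synthetic_kick_experiment(seed) for seed in range(1, 11)]


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
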