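import numpy as np
import pytest
from hypothesis import settings

from polyunwrap import WrappedVolume, simulate_gaussian_dataset

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def smooth_phantom():
    """Noiseless wrapped Gaussian-bump phantom (one full wrap, 32³)."""
    ds = simulate_gaussian_dataset(shape=(32, 32, 32), gaussian_sd=6.4,
                                   peak=10.0, noise_sd=0.0, seed=0)
    return ds


@pytest.fixture(scope="session")
def noisy_phantom():
    """Moderate-noise (SNR 2.5) miniature Gaussian-bump phantom."""
    ds = simulate_gaussian_dataset(shape=(40, 40, 40), gaussian_sd=8.0,
                                   peak=8.0, magnitude=50.0, noise_sd=20.0,
                                   seed=np.random.SeedSequence(entropy=42))
    return ds


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def constant_volume():
    """20³ volume with constant phase 0.1 rad."""
    return WrappedVolume(np.full((20, 20, 20), 0.1))
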