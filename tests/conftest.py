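import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite", deadline=None, derandomize=True, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("suite")

from hyperssc import SpectralModel, generate_dataset


@pytest.fixture(scope="session")
def small_model():
    """64-band spectral model: cheap but spectrally faithful."""
    return SpectralModel(n_bands=64)


@pytest.fixture(scope="session")
def noiseless_model():
    return SpectralModel(n_bands=64, noise_sd=0.0)


@pytest.fixture(scope="session")
def small_dataset(small_model):
    """20 samples per stage, 80 total."""
    return generate_dataset(n_per_stage=20, model=small_model, seed=11)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
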