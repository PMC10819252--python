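import numpy as np
import pytest

from leafspec import GeneratorConfig, SpectralAxis, generate_dataset


@pytest.fixture(scope="session")
def small_config() -> GeneratorConfig:
    """Reduced-axis generator config used by most search tests."""
    return GeneratorConfig(n_bands=40, n_samples=60, seed=7)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return generate_dataset(small_config)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture()
def tiny_axis() -> SpectralAxis:
    return SpectralAxis(np.array([450.0, 625.0, 800.0]))
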