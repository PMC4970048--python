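import numpy as np
import pytest

from graintex.synthetic import GranularImageSpec, generate_granular_image


@pytest.fixture(scope="session")
def random_image():
    """Seeded 64x64 standard-normal image for convolution oracles."""
    return np.random.default_rng(42).normal(size=(64, 64))


@pytest.fixture(scope="session")
def grain_image():
    """Default 128x128 synthetic grain image (isotropic particle orientation)."""
    return generate_granular_image(GranularImageSpec(seed=3))


@pytest.fixture(scope="session")
def small_grain_image():
    """96x96 grain image for cheaper feature-extraction tests."""
    return generate_granular_image(
        GranularImageSpec(shape=(96, 96), n_particles=90, seed=11)
    )
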