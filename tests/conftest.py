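import numpy as np
import pytest

from lungprep import BinaryMask, PhantomSpec, generate_phantom


def mask(arr) -> BinaryMask:
    return BinaryMask(np.asarray(arr, dtype=np.uint8))


def random_mask(rng: np.random.Generator, shape=(32, 32), p=0.5) -> BinaryMask:
    return BinaryMask((rng.random(shape) < p).astype(np.uint8))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240915)


@pytest.fixture
def clean_phantom():
    """Noiseless default-geometry phantom (512x512)."""
    return generate_phantom(PhantomSpec(seed=7, noise_sigma=0.0))


@pytest.fixture
def small_phantom():
    """Noiseless 128x128 phantom for fast unit tests."""
    return generate_phantom(PhantomSpec(size=(128, 128), seed=7, noise_sigma=0.0))
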