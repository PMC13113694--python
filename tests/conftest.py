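import numpy as np
import pytest

from ctenhance import (
    PhantomConfig,
    extract_patch,
    generate_candidates,
    generate_volume,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def phantom_pair():
    """One medium phantom with its truth record (session-cached)."""
    config = PhantomConfig(seed=3)
    return generate_volume(config)


@pytest.fixture(scope="session")
def calibration_patches(phantom_pair):
    """Six candidate-centered [0, 1] patches from the session phantom."""
    volume, truth = phantom_pair
    cands = generate_candidates(truth, volume, n_negatives=6, seed=4)
    return [extract_patch(volume, c).pixels for c in cands[:6]]


@pytest.fixture(scope="session")
def small_phantom_pair():
    """A small, fast phantom for I/O and geometry tests."""
    config = PhantomConfig(
        shape=(24, 48, 48),
        nodule_count=1,
        nodule_radius_range=(2.0, 3.0),
        vessel_count=2,
        noise_sd=5.0,
        seed=7,
    )
    return generate_volume(config)
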