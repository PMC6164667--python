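import numpy as np
import pytest

from hippotex import QuantizedRoi, Volume, spherical_mask


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def noise_volume(rng):
    """A 21^3 volume of Gaussian noise around a typical MR intensity."""
    return Volume(rng.normal(1000.0, 100.0, (21, 21, 21)))


@pytest.fixture
def center_sphere():
    return spherical_mask((21, 21, 21), (10, 10, 10), 5.0)


def random_quantized(rng, shape, n_levels, p_valid=0.85) -> QuantizedRoi:
    """Random small quantized grid with holes, for oracle comparisons."""
    while True:
        valid = rng.random(shape) < p_valid
        if valid.any():
            break
    levels = np.where(valid, rng.integers(1, n_levels + 1, shape), 0)
    return QuantizedRoi(levels=levels, valid=valid, n_levels=n_levels)
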