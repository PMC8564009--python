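import numpy as np
import pytest

from msibeef.cube import MultispectralCube, RoiMask


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def calibrated_cube(rng):
    """Random calibrated 16x16x6 cube with the standard band centers."""
    pixels = rng.uniform(0.05, 0.95, size=(16, 16, 6))
    return MultispectralCube(pixels, is_calibrated=True)


@pytest.fixture
def full_roi():
    return RoiMask(np.ones((16, 16), dtype=bool))
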