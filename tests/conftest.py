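import numpy as np
import pytest


@pytest.fixture
def ramp_x():
    """64x64 image I(x, y) = x (column index)."""
    return np.tile(np.arange(64, dtype=np.float64), (64, 1))


@pytest.fixture
def coords64():
    """Column (x) and row (y) index grids of a 64x64 frame."""
    y, x = np.mgrid[0:64, 0:64].astype(np.float64)
    return x, y


@pytest.fixture
def interior():
    """Slice selecting pixels at least 13 px from every border
    (covers kernel radius ceil(3*sigma) up to sigma=4)."""
    return (slice(13, -13), slice(13, -13))


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
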