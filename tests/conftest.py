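import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from zonegrade.io_preprocess import ROIFragment


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_fragment(rng):
    """A generic 61x61 fragment with continuous intensities."""
    return ROIFragment(rng.normal(100.0, 15.0, size=(61, 61)))


@pytest.fixture
def ramp_slice():
    """A 100x100 slice whose pixel (r, c) equals 100*r + c."""
    from zonegrade.io_preprocess import ImageSlice2D

    r, c = np.meshgrid(np.arange(100), np.arange(100), indexing="ij")
    return ImageSlice2D((100 * r + c).astype(float), 0.5, 0.5)
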