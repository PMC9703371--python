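import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from gelspot.io_gel import GelImage


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def gel(pixels) -> GelImage:
    """Wrap a raw array as an in-memory GelImage."""
    return GelImage(np.asarray(pixels, dtype=np.float64))


@pytest.fixture
def ramp4() -> GelImage:
    """4x4 ramp: pixel value = (row*4 + col) / 15."""
    return gel(np.arange(16, dtype=np.float64).reshape(4, 4) / 15.0)
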