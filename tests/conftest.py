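import numpy as np
import pytest

from myeliq.io import Micrograph
from myeliq.segmentation import BinaryMask


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_micrograph(rng):
    px = rng.integers(0, 256, size=(32, 32), dtype=np.uint8)
    return Micrograph(px, 8, 0.5, "random32")


def as_micrograph(arr, pixel_size=1.0, bit_depth=8, source_id="fixture"):
    dtype = np.uint8 if bit_depth == 8 else np.uint16
    return Micrograph(np.asarray(arr, dtype=dtype), bit_depth, pixel_size, source_id)


def as_mask(arr, pixel_size=1.0):
    return BinaryMask(np.asarray(arr, dtype=bool), pixel_size)
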