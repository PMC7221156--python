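import numpy as np
import pytest

from repeatomics import RegionMask, ScanVolume, build_catalog


def make_volume(arr, spacing=(1.0, 1.0, 1.0), origin=(0.0, 0.0, 0.0), **kw):
    return ScanVolume(np.asarray(arr, dtype=float), spacing, origin, **kw)


def make_mask(arr, spacing=(1.0, 1.0, 1.0), origin=(0.0, 0.0, 0.0), **kw):
    return RegionMask(np.asarray(arr), spacing, origin, **kw)


@pytest.fixture(scope="session")
def catalog():
    return build_catalog()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_quantized_roi(rng, shape=(4, 4, 4), Ng=4, spacing=(1.0, 1.0, 1.0)):
    """A random fully-foreground quantized ROI for oracle comparisons."""
    from repeatomics.features.texture import QuantizedROI

    levels = rng.integers(1, Ng + 1, size=shape).astype(np.int32)
    mask = make_mask(np.ones(shape), spacing)
    return QuantizedROI(levels, Ng, mask, spacing)
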