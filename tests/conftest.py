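import numpy as np
import pytest

from lesionbench import BinaryMask, ImageVolume


def make_volume(values, affine=None, id="vol"):
    """A 3-D volume from a 1-D list laid out along the first axis."""
    arr = np.asarray(values, dtype=float).reshape(-1, 1, 1)
    if affine is None:
        affine = np.eye(4)
    return ImageVolume(data=arr, affine=np.asarray(affine, float), id=id)


def make_mask(flags, affine=None, id="mask"):
    arr = np.asarray(flags, dtype=np.uint8).reshape(-1, 1, 1)
    if affine is None:
        affine = np.eye(4)
    return BinaryMask(data=arr, affine=np.asarray(affine, float), id=id)


@pytest.fixture
def anisotropic_affine():
    """1 x 0.5 x 0.5 mm voxel grid (0.25 mm³ per voxel)."""
    A = np.eye(4)
    A[1, 1] = 0.5
    A[2, 2] = 0.5
    return A


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
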