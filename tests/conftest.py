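import numpy as np
import pytest

from decm.volumes import Mask3D, Volume4D


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_volume(rng):
    """10x10x10x20 volume with positive values (valid for minima masking)."""
    data = rng.uniform(100.0, 1000.0, size=(10, 10, 10, 20))
    return Volume4D(data=data, affine=np.diag([3.0, 3.0, 3.0, 1.0]), voxel_size=(3, 3, 3), tr=2.5)


@pytest.fixture
def ball_mask():
    """Small spherical mask on an 8x8x8 grid."""
    xi, yi, zi = np.meshgrid(*[np.arange(8)] * 3, indexing="ij")
    r = (xi - 3.5) ** 2 + (yi - 3.5) ** 2 + (zi - 3.5) ** 2
    return Mask3D(data=(r <= 9.0), affine=np.eye(4))
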