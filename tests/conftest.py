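import numpy as np
import pytest

from cisplan import ModelParams, TumorMask, make_sphere_mask


@pytest.fixture(scope="session")
def params():
    return ModelParams()


@pytest.fixture(scope="session")
def sphere1():
    """1 cm^3 sphere at the default 1 mm spacing (~1000 voxels)."""
    return make_sphere_mask(1.0)


@pytest.fixture(scope="session")
def sphere4():
    return make_sphere_mask(4.0)


@pytest.fixture
def line_mask():
    """A 1-voxel-thick line of 21 voxels along z at 1 mm spacing.

    Useful for probing the kernel at exact distances: voxel k sits
    k mm from voxel 0.
    """
    occ = np.zeros((1, 1, 21), dtype=bool)
    occ[0, 0, :] = True
    return TumorMask(occ, (1.0, 1.0, 1.0))


@pytest.fixture
def box3():
    """3x3x3 fully occupied box at 2 mm spacing (27 voxels)."""
    return TumorMask(np.ones((3, 3, 3), dtype=bool), (2.0, 2.0, 2.0))
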