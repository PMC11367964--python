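import numpy as np
import pytest

from replanar import (ActivityVolume, GridGeometry, MuMap, PhantomSpec,
                      make_phantom)


@pytest.fixture(scope="session")
def small_grid():
    """16-cube grid covering the same physical field as the default phantom."""
    return GridGeometry((16, 16, 16), voxel_size_mm=19.68)


@pytest.fixture(scope="session")
def default_phantom():
    """One deterministic default phantom (activity, mu, truth)."""
    return make_phantom(PhantomSpec(), seed=11)


@pytest.fixture(scope="session")
def small_phantom(small_grid):
    """Coarse phantom for reconstruction tests."""
    spec = PhantomSpec(grid=small_grid, myo_to_rib_ratio=1.5)
    return make_phantom(spec, seed=3)


@pytest.fixture()
def uniform_volumes(small_grid):
    """Uniform activity and attenuation on the small grid."""
    act = ActivityVolume(np.full(small_grid.shape, 2.0), small_grid)
    mu = MuMap(np.full(small_grid.shape, 0.005), small_grid)
    return act, mu
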