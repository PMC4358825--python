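import numpy as np
import pytest

from fluoroquant.phantom import (
    AcquisitionParams,
    PelletSpec,
    PhantomSpec,
    ReferenceTubeSpec,
    VoxelGrid,
)


@pytest.fixture
def grid():
    return VoxelGrid(dims=(32, 32, 16), voxel_size_mm=(1.0, 1.0, 2.0))


@pytest.fixture
def single_pellet_spec(grid):
    """One 10⁶-cell pellet plus reference tube on the default grid."""
    return PhantomSpec(
        grid=grid,
        pellets=(PelletSpec(center_mm=(10.0, 16.0, 16.0), radius_mm=3.0,
                            n_cells=1_000_000, spins_per_cell=1.5e11),),
        reference=ReferenceTubeSpec(center_mm=(24.0, 16.0, 16.0),
                                    radius_mm=2.0, length_mm=16.0),
    )


@pytest.fixture
def noise_free_acq():
    return AcquisitionParams(noise_sd=0.0, gain=1e-12, seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
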