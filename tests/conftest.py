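import numpy as np
import pytest

from cellvol3d.phantoms import CellTruth, PhantomSpec, generate_phantom_stack


@pytest.fixture(scope="session")
def two_cell_phantom():
    """Two well-separated spherical tumor cells, no noise, 0.5 um voxels."""
    cells = [
        CellTruth(center=(12.0, 8.0, 8.0), cell_volume=600.0,
                  nuclear_volume=200.0, ploidy=2.0),
        CellTruth(center=(12.0, 8.0, 22.0), cell_volume=900.0,
                  nuclear_volume=320.0, ploidy=4.0),
    ]
    spec = PhantomSpec(stack_shape=(48, 32, 60), voxel_size=(0.5, 0.5, 0.5),
                       cells=cells, rng_seed=7)
    stack, cell_labels, nucleus_labels = generate_phantom_stack(spec)
    return spec, stack, cell_labels, nucleus_labels


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
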