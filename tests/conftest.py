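import numpy as np
import pytest

from isquant import CellParams, ImageStack, generate_coverslip_cell, segment_cell


def make_stack(arrays, voxel_size=(0.14, 0.2, 0.2), roles=None):
    """Assemble an ImageStack from one 3-D array per channel role."""
    if isinstance(arrays, np.ndarray):
        arrays = [arrays]
    roles = roles if roles is not None else {"er": 0}
    return ImageStack(
        voxels=np.stack([np.asarray(a, dtype=np.float64) for a in arrays]),
        voxel_size=voxel_size,
        channel_roles=roles,
    )


@pytest.fixture(scope="session")
def default_cell():
    """One coverslip cell at default parameters and noise."""
    return generate_coverslip_cell(seed=11)


@pytest.fixture(scope="session")
def default_seg(default_cell):
    return segment_cell(default_cell[0], "actin")


@pytest.fixture(scope="session")
def noisefree_cell():
    params = CellParams(poisson_noise=False, gaussian_sigma=0.0)
    return generate_coverslip_cell(params, seed=11)
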