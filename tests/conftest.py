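import numpy as np
import pytest

from lungrp.geometry import DoseGrid, StructureMask
from lungrp.synthetic_data import CohortConfig, PhantomConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_phantom_config():
    """Coarse phantom that keeps distance transforms fast."""
    return PhantomConfig(shape=(36, 44, 44), spacing_mm=(4.0, 4.0, 4.0),
                         lung_centers_mm=((72, 88, 48), (72, 88, 128)),
                         lung_semi_axes_mm=(58, 50, 32),
                         gtv_center_mm=(72, 88, 120), gtv_radius_mm=16.0)


@pytest.fixture(scope="session")
def default_cohort():
    return simulate_cohort(CohortConfig(seed=12345))


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


def random_grid_and_mask(rng, shape, spacing=(1.0, 1.0, 1.0), max_dose=40.0, p_mask=0.3):
    dose = DoseGrid(rng.uniform(0.0, max_dose, shape), spacing)
    voxels = rng.random(shape) < p_mask
    voxels.flat[0] = True  # never empty
    return dose, StructureMask("m", voxels, spacing)


def brute_force_dilation(voxels, spacing, margin_mm, chunk=4096):
    """Per-voxel nearest-distance oracle for Euclidean margin expansion."""
    coords = np.argwhere(voxels) * np.asarray(spacing)
    all_idx = np.indices(voxels.shape).reshape(3, -1).T * np.asarray(spacing)
    out = np.empty(all_idx.shape[0], dtype=bool)
    r2 = margin_mm ** 2 * (1 + 1e-9) + 1e-6
    for start in range(0, all_idx.shape[0], chunk):
        block = all_idx[start:start + chunk]
        d2 = ((block[:, None, :] - coords[None, :, :]) ** 2).sum(axis=2)
        out[start:start + chunk] = d2.min(axis=1) <= r2
    return out.reshape(voxels.shape)
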