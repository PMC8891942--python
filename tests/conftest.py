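import numpy as np
import pytest

from pasym.io_core import BoldDataset, BrainMask
from pasym.pas import label_hemispheres
from pasym.simulate import SimDesign, make_mask


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def small_mask():
    """6x4x4 full-box mask, world x centered on 0 (no midline voxels)."""
    return make_mask(SimDesign(shape=(6, 4, 4)))


@pytest.fixture
def small_labeling(small_mask):
    return label_hemispheres(small_mask)


@pytest.fixture
def small_bold(small_mask, rng):
    v = small_mask.n_voxels
    return BoldDataset(
        subject_id="sub-test",
        data=rng.normal(size=(80, v)),
        voxel_coords=small_mask.voxel_coords,
        affine=small_mask.affine,
        tr_seconds=2.0,
    )


def random_instance(rng, shape=None, n_time=30, zero_var_frac=0.0):
    """A random (mask, labeling, bold) triple for oracle-equivalence tests."""
    if shape is None:
        nx = int(rng.integers(2, 4)) * 2 + int(rng.integers(0, 2))  # 4..7
        shape = (nx, int(rng.integers(2, 4)), int(rng.integers(2, 4)))
    mask = make_mask(SimDesign(shape=shape))
    labeling = label_hemispheres(mask)
    data = rng.normal(size=(n_time, mask.n_voxels))
    # correlated structure so many pairs cross the threshold
    shared = rng.normal(size=(n_time, 1))
    data = data + shared * rng.uniform(0, 1.5, mask.n_voxels)
    if zero_var_frac > 0:
        k = max(1, int(zero_var_frac * mask.n_voxels))
        cols = rng.choice(mask.n_voxels, k, replace=False)
        data[:, cols] = rng.uniform(-1, 1, k)
    bold = BoldDataset(
        subject_id="sub-rand",
        data=data,
        voxel_coords=mask.voxel_coords,
        affine=mask.affine,
        tr_seconds=2.0,
    )
    return mask, labeling, bold
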