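"""On-disk formats and shared domain types.

Volumes are NIfTI-1 (optionally gzipped); tables are tab-separated UTF-8
with a header row and empty fields for missing values.  All voxel
bookkeeping uses a fixed row-major ordering over the mask grid so that
per-voxel vectors are comparable across subjects sharing a mask.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

GROUPS = ("GI_MDD", "NGI_MDD", "HC")
GENDERS = ("male", "female")

#: columns a subject table must always carry
SUBJECT_REQUIRED = ("subject_id", "group", "age", "gender", "education", "mean_fd")

#: optional clinical columns (absent or empty for controls where noted)
SUBJECT_CLINICAL = (
    "illness_duration",
    "hrsd17_total",
    "anxiety_somatization",
    "weight_loss",
    "cognitive_disturbance",
    "retardation",
    "sleep_disturbance",
    "gi_item",
)

MOTION_COLUMNS = ("trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z")


class PasymError(Exception):
    """Base class for all package errors."""


class GridMismatchError(PasymError):
    """A volume's grid or affine does not match the reference mask."""


class ValidationError(PasymError):
    """A table or config failed validation."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class BrainMask:
    """Boolean voxel-inclusion grid plus the grid-to-world affine."""

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=bool)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 3:
            raise ValidationError(f"mask must be 3-D, got shape {self.data.shape}")
        if self.affine.shape != (4, 4):
            raise ValidationError("affine must be 4x4")
        if not self.data.any():
            raise ValidationError("mask has no in-mask voxels")
        if abs(np.linalg.det(self.affine)) < 1e-12:
            raise ValidationError("mask affine is singular")

    @property
    def shape(self) -> tuple:
        return self.data.shape

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    @property
    def voxel_coords(self) -> np.ndarray:
        """(V, 3) integer grid coordinates of in-mask voxels, row-major order."""
        return np.argwhere(self.data)

    def world_coords(self) -> np.ndarray:
        """(V, 3) world-mm coordinates of in-mask voxel centers."""
        ijk = self.voxel_coords
        homog = np.column_stack([ijk, np.ones(len(ijk))])
        return (homog @ self.affine.T)[:, :3]


@dataclass
class BoldDataset:
    """One subject's masked time-by-voxel BOLD matrix.

    ``frame_keep_mask`` marks frames retained after scrubbing; correlation
    code uses only retained frames.
    """

    subject_id: str
    data: np.ndarray  # (T, V)
    voxel_coords: np.ndarray  # (V, 3) grid indices
    affine: np.ndarray  # 4x4 grid->world
    tr_seconds: float
    frame_keep_mask: np.ndarray = None  # (T,) bool

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValidationError("BOLD data must be time-by-voxel")
        if self.tr_seconds <= 0:
            raise ValidationError("tr_seconds must be positive")
        if self.data.shape[0] < 2:
            raise ValidationError("need at least 2 time points")
        if self.frame_keep_mask is None:
            self.frame_keep_mask = np.ones(self.data.shape[0], dtype=bool)
        self.frame_keep_mask = np.asarray(self.frame_keep_mask, dtype=bool)
        if self.frame_keep_mask.shape != (self.data.shape[0],):
            raise ValidationError("frame_keep_mask length must match time dimension")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.data.shape[1]

    @property
    def n_retained(self) -> int:
        return int(self.frame_keep_mask.sum())

    def retained(self) -> np.ndarray:
        """Time-by-voxel matrix restricted to retained frames."""
        return self.data[self.frame_keep_mask]

    def replace(self, **kw) -> "BoldDataset":
        return dataclasses.replace(self, **kw)


@dataclass
class MotionTrace:
    """Six rigid-body parameters per time point (translations mm, rotations rad)."""

    subject_id: str
    params: np.ndarray  # (T, 6)

    def __post_init__(self) -> None:
        self.params = np.asarray(self.params, dtype=float)
        if self.params.ndim != 2 or self.params.shape[1] != 6:
            raise ValidationError("motion parameters must be (T, 6)")
        if not np.isfinite(self.params).all():
            raise ValidationError("motion parameters contain non-finite values")

    @property
    def n_frames(self) -> int:
        return self.params.shape[0]

    @property
    def translations(self) -> np.ndarray:
        return self.params[:, :3]

    @property
    def rotations(self) -> np.ndarray:
        return self.params[:, 3:]


@dataclass
class SubjectTable:
    """Per-subject group labels, covariates, and clinical scores."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in SUBJECT_REQUIRED if c not in self.df.columns]
        if missing:
            raise ValidationError(f"subject table missing column(s): {', '.join(missing)}")
        bad_group = ~self.df["group"].isin(GROUPS)
        if bad_group.any():
            rows = self.df.index[bad_group].tolist()
            raise ValidationError(f"unknown group label in rows {rows}")
        bad_gender = ~self.df["gender"].isin(GENDERS)
        if bad_gender.any():
            rows = self.df.index[bad_gender].tolist()
            raise ValidationError(f"unknown gender label in rows {rows}")
        self.df = self.df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def groups(self) -> pd.Series:
        return self.df["group"]

    def subset(self, groups: Sequence[str]) -> "SubjectTable":
        sub = self.df[self.df["group"].isin(groups)].reset_index(drop=True)
        return SubjectTable(sub)

    def require_covariates(self, names: Sequence[str]) -> None:
        """Raise if any named covariate is absent or has missing values."""
        for name in names:
            if name not in self.df.columns:
                raise ValidationError(f"covariate column missing: {name}")
            col = self.df[name]
            if col.isna().any():
                rows = self.df.index[col.isna()].tolist()
                raise ValidationError(f"covariate {name!r} missing in rows {rows}")


@dataclass
class RunConfig:
    """All analysis thresholds in one declarative record."""

    fc_threshold: float = 0.2
    fd_scrub_threshold_mm: float = 0.2
    bandpass_hz: tuple = (0.01, 0.08)
    max_translation_mm: float = 2.0
    max_rotation_deg: float = 2.0
    alpha_fdr: float = 0.05
    cluster_connectivity: int = 26
    min_cluster_extent: int = 0
    svm_kernel: str = "rbf"
    svm_cost: float = 1.0
    svm_gamma: str = "scale"
    drop_initial_volumes: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        self.bandpass_hz = tuple(float(v) for v in self.bandpass_hz)
        if not 0 <= self.fc_threshold < 1:
            raise ValidationError("fc_threshold must lie in [0, 1)")
        low, high = self.bandpass_hz
        if not 0 < low < high:
            raise ValidationError("bandpass must satisfy 0 < low < high")
        if self.cluster_connectivity not in (6, 18, 26):
            raise ValidationError("cluster_connectivity must be 6, 18 or 26")
        if self.min_cluster_extent < 0:
            raise ValidationError("min_cluster_extent must be non-negative")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        payload = dataclasses.asdict(self)
        payload["bandpass_hz"] = list(self.bandpass_hz)
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=True)

    def as_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["bandpass_hz"] = list(self.bandpass_hz)
        return d


# ---------------------------------------------------------------------------
# volume I/O
# ---------------------------------------------------------------------------


def read_mask(path) -> BrainMask:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    return BrainMask(data > 0, img.affine)


def write_mask(mask: BrainMask, path) -> None:
    img = nib.Nifti1Image(mask.data.astype(np.uint8), mask.affine)
    nib.save(img, str(path))


def _check_grid(shape3, affine, mask: BrainMask, path) -> None:
    if tuple(shape3) != tuple(mask.shape):
        raise GridMismatchError(
            f"{path}: grid {tuple(shape3)} does not match mask grid {tuple(mask.shape)}"
        )
    if not np.allclose(affine, mask.affine, atol=1e-4):
        raise GridMismatchError(f"{path}: affine does not match mask affine")


def read_bold(path, mask: BrainMask, tr_seconds: float | None = None,
              subject_id: str | None = None) -> BoldDataset:
    """Load a 4-D NIfTI and extract the in-mask time-by-voxel matrix."""
    img = nib.load(str(path))
    if img.ndim != 4:
        raise PasymError(f"{path}: expected a 4-D volume, got {img.ndim}-D")
    _check_grid(img.shape[:3], img.affine, mask, path)
    if img.shape[3] < 2:
        raise PasymError(f"{path}: fewer than 2 time points")
    vol = np.asarray(img.dataobj, dtype=float)
    data = vol[mask.data].T  # (T, V) with row-major voxel order
    if tr_seconds is None:
        tr_seconds = float(img.header.get_zooms()[3]) or 1.0
    if subject_id is None:
        subject_id = Path(path).name.split(".")[0]
    return BoldDataset(
        subject_id=subject_id,
        data=data,
        voxel_coords=mask.voxel_coords,
        affine=mask.affine,
        tr_seconds=tr_seconds,
    )


def write_bold(bold: BoldDataset, mask: BrainMask, path) -> None:
    """Place the time-by-voxel matrix back into the mask grid and save."""
    if bold.n_voxels != mask.n_voxels:
        raise PasymError(
            f"voxel count {bold.n_voxels} does not match mask ({mask.n_voxels})"
        )
    vol = np.zeros(mask.shape + (bold.n_frames,), dtype=np.float64)
    vol[mask.data] = bold.data.T
    img = nib.Nifti1Image(vol, mask.affine)
    img.header.set_zooms(img.header.get_zooms()[:3] + (bold.tr_seconds,))
    nib.save(img, str(path))


def write_stat_map(values, mask: BrainMask, path) -> None:
    """Write one value per in-mask voxel into a 3-D volume (zeros elsewhere)."""
    values = np.asarray(values, dtype=float)
    if values.shape != (mask.n_voxels,):
        raise PasymError(
            f"expected {mask.n_voxels} values, got {values.shape}"
        )
    vol = np.zeros(mask.shape, dtype=np.float64)
    vol[mask.data] = values
    nib.save(nib.Nifti1Image(vol, mask.affine), str(path))


def read_stat_map(path, mask: BrainMask) -> np.ndarray:
    img = nib.load(str(path))
    if img.ndim != 3:
        raise PasymError(f"{path}: expected a 3-D volume")
    _check_grid(img.shape, img.affine, mask, path)
    return np.asarray(img.dataobj, dtype=float)[mask.data]


# ---------------------------------------------------------------------------
# tabular I/O
# ---------------------------------------------------------------------------


def read_subject_table(path) -> SubjectTable:
    df = pd.read_csv(path, sep="\t")
    return SubjectTable(df)


def write_subject_table(table: SubjectTable, path) -> None:
    table.df.to_csv(path, sep="\t", index=False)


def read_motion(path, subject_id: str | None = None) -> MotionTrace:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in MOTION_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"motion file missing column(s): {', '.join(missing)}")
    if subject_id is None:
        subject_id = Path(path).name.split(".")[0]
    return MotionTrace(subject_id, df[list(MOTION_COLUMNS)].to_numpy(float))


def write_motion(motion: MotionTrace, path) -> None:
    pd.DataFrame(motion.params, columns=list(MOTION_COLUMNS)).to_csv(
        path, sep="\t", index=False
    )
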