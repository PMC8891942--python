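"""Hemisphere labeling and the voxel-wise connectivity-asymmetry score.

For every non-midline voxel the score is the difference between its mean
Fisher-z correlation with supra-threshold voxels in the opposite
hemisphere and the corresponding mean within its own hemisphere.  Only
positive correlations above the threshold contribute; near-perfect
correlations (|r| >= 0.999999, i.e. duplicated series) are treated like
self-correlations and dropped from partner sets so that mirrored copies
cannot inject unbounded z values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_core import BoldDataset, BrainMask, PasymError

LEFT = -1
RIGHT = 1
EXCLUDED = 0

#: correlations at or beyond this magnitude are considered degenerate
R_CLIP = 0.999999


@dataclass
class HemisphereLabeling:
    """Per in-mask voxel: side (-1 left, +1 right, 0 excluded midline) and
    the index of the homotopic mirror partner (-1 when absent)."""

    side: np.ndarray
    mirror_index: np.ndarray

    def __post_init__(self) -> None:
        self.side = np.asarray(self.side, dtype=np.int8)
        self.mirror_index = np.asarray(self.mirror_index, dtype=np.int64)
        if self.side.shape != self.mirror_index.shape:
            raise PasymError("side and mirror_index must align")

    @property
    def n_voxels(self) -> int:
        return self.side.size

    @property
    def nonexcluded_index(self) -> np.ndarray:
        return np.flatnonzero(self.side != EXCLUDED)

    def counts(self) -> dict:
        return {
            "left": int((self.side == LEFT).sum()),
            "right": int((self.side == RIGHT).sum()),
            "excluded": int((self.side == EXCLUDED).sum()),
        }


@dataclass
class PASMap:
    """Asymmetry score and its two components for non-excluded voxels.

    ``voxel_index`` maps rows back into the in-mask voxel ordering.
    """

    voxel_index: np.ndarray
    pas: np.ndarray
    fc_inter: np.ndarray
    fc_intra: np.ndarray
    n_inter_used: np.ndarray
    n_intra_used: np.ndarray

    def to_full(self, n_voxels: int, fill: float = 0.0) -> np.ndarray:
        """Scatter the score back to a length-``n_voxels`` in-mask vector."""
        out = np.full(n_voxels, fill, dtype=float)
        out[self.voxel_index] = self.pas
        return out


def label_hemispheres(mask: BrainMask, mirror_tol_mm: float = 1e-3) -> HemisphereLabeling:
    """Assign in-mask voxels to hemispheres by the sign of world-space x.

    Negative x is left.  Voxel centers within half a voxel width of the
    x = 0 plane are excluded from both hemispheres.  Mirror partners are
    matched by reflecting the center across x = 0 (within tolerance).
    """
    world = mask.world_coords()
    half_width = 0.5 * float(np.linalg.norm(mask.affine[:3, 0]))
    x = world[:, 0]
    side = np.where(np.abs(x) < half_width, EXCLUDED, np.sign(x)).astype(np.int8)
    if not (side == LEFT).any() or not (side == RIGHT).any():
        raise PasymError("a hemisphere has zero voxels; asymmetry is undefined")

    decimals = max(0, int(-np.floor(np.log10(mirror_tol_mm))))
    keys = {tuple(np.round(c, decimals)): i for i, c in enumerate(world)}
    mirror = np.full(len(world), -1, dtype=np.int64)
    for i, c in enumerate(world):
        if side[i] == EXCLUDED:
            continue
        j = keys.get(tuple(np.round([-c[0], c[1], c[2]], decimals)))
        if j is not None and side[j] == -side[i]:
            mirror[i] = j
    return HemisphereLabeling(side, mirror)


def _standardized_columns(bold: BoldDataset) -> tuple[np.ndarray, np.ndarray]:
    """Unit-norm centered columns over retained frames; zero-variance
    voxels become all-zero columns (their correlations read as 0)."""
    if bold.n_retained < 3:
        raise PasymError(
            f"{bold.subject_id}: only {bold.n_retained} retained frames; need >= 3"
        )
    x = bold.retained()
    xc = x - x.mean(axis=0)
    norms = np.sqrt((xc**2).sum(axis=0))
    # constant columns center to rounding noise, not exact zeros; compare
    # against the raw column norm so they are treated as zero-variance
    raw = np.sqrt((x**2).sum(axis=0))
    valid = norms > 1e-8 * raw
    xn = np.where(valid, xc / np.where(valid, norms, 1.0), 0.0)
    return xn, valid


def compute_pas(
    bold: BoldDataset,
    labeling: HemisphereLabeling,
    fc_threshold: float = 0.2,
    block_size: int = 256,
) -> PASMap:
    """Blocked computation of the asymmetry score for every non-excluded voxel.

    Processes target voxels in blocks so the full voxel-by-voxel
    correlation matrix is never materialized; results are identical to
    the naive reference implementation.
    """
    if not 0 <= fc_threshold < 1:
        raise PasymError("fc_threshold must lie in [0, 1)")
    if labeling.n_voxels != bold.n_voxels:
        raise PasymError("labeling does not match BOLD voxel count")
    xn, valid = _standardized_columns(bold)
    if not valid.any():
        raise PasymError(f"{bold.subject_id}: all voxel series have zero variance")

    idx = labeling.nonexcluded_index
    side = labeling.side[idx]
    cols = xn[:, idx]  # (Tk, M)
    m = idx.size

    pas = np.zeros(m)
    fc_inter = np.zeros(m)
    fc_intra = np.zeros(m)
    n_inter = np.zeros(m, dtype=np.int64)
    n_intra = np.zeros(m, dtype=np.int64)

    opposite = side[None, :]  # broadcast against each block row's side
    for start in range(0, m, block_size):
        stop = min(start + block_size, m)
        r = cols[:, start:stop].T @ cols  # (b, M)
        surv = (r > fc_threshold) & (r < R_CLIP)
        rows = np.arange(start, stop)
        surv[rows - start, rows] = False  # self never in its own partner set
        z = np.arctanh(np.clip(r, -R_CLIP, R_CLIP))
        inter = opposite != side[start:stop, None]
        si = surv & inter
        sa = surv & ~inter
        ni = si.sum(axis=1)
        na = sa.sum(axis=1)
        with np.errstate(invalid="ignore"):
            fi = np.where(ni > 0, (z * si).sum(axis=1) / np.maximum(ni, 1), 0.0)
            fa = np.where(na > 0, (z * sa).sum(axis=1) / np.maximum(na, 1), 0.0)
        fc_inter[start:stop] = fi
        fc_intra[start:stop] = fa
        n_inter[start:stop] = ni
        n_intra[start:stop] = na
        pas[start:stop] = fi - fa

    return PASMap(idx.copy(), pas, fc_inter, fc_intra, n_inter, n_intra)


def pas_oracle(
    bold: BoldDataset, labeling: HemisphereLabeling, fc_threshold: float = 0.2
) -> PASMap:
    """Naive loop-based reference implementation (tests only; small inputs)."""
    if not 0 <= fc_threshold < 1:
        raise PasymError("fc_threshold must lie in [0, 1)")
    if labeling.n_voxels != bold.n_voxels:
        raise PasymError("labeling does not match BOLD voxel count")
    if bold.n_voxels > 200:
        raise PasymError("oracle is restricted to <= 200 voxels")
    xn, valid = _standardized_columns(bold)
    if not valid.any():
        raise PasymError(f"{bold.subject_id}: all voxel series have zero variance")

    idx = labeling.nonexcluded_index
    side = labeling.side
    m = idx.size
    pas = np.zeros(m)
    fc_inter = np.zeros(m)
    fc_intra = np.zeros(m)
    n_inter = np.zeros(m, dtype=np.int64)
    n_intra = np.zeros(m, dtype=np.int64)

    for row, v in enumerate(idx):
        inter_z, intra_z = [], []
        for w in idx:
            if w == v:
                continue
            r = float(xn[:, v] @ xn[:, w])
            if not (fc_threshold < r < R_CLIP):
                continue
            z = float(np.arctanh(np.clip(r, -R_CLIP, R_CLIP)))
            if side[w] == side[v]:
                intra_z.append(z)
            else:
                inter_z.append(z)
        fc_inter[row] = np.mean(inter_z) if inter_z else 0.0
        fc_intra[row] = np.mean(intra_z) if intra_z else 0.0
        n_inter[row] = len(inter_z)
        n_intra[row] = len(intra_z)
        pas[row] = fc_inter[row] - fc_intra[row]

    return PASMap(idx.copy(), pas, fc_inter, fc_intra, n_inter, n_intra)


def group_pas_stack(
    datasets: list,
    labeling: HemisphereLabeling,
    fc_threshold: float = 0.2,
) -> np.ndarray:
    """Subject-by-voxel score matrix (rows follow the dataset order)."""
    rows = []
    for ds in datasets:
        try:
            rows.append(compute_pas(ds, labeling, fc_threshold).pas)
        except PasymError as exc:
            raise PasymError(f"subject {ds.subject_id}: {exc}") from exc
    return np.vstack(rows)
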