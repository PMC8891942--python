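"""Synthetic two-hemisphere BOLD cohorts with analytic correlation structure.

Each voxel series is a latent-factor mixture

    x_v(t) = alpha_v * s_pair(v) + beta * s_hemi(side(v)) + sigma * e_v(t)

where ``s_pair`` is shared exactly by a voxel and its mirror partner and
``s_hemi`` by all voxels of one side.  With unit-variance independent
latents the expected correlations are closed-form:

    r_pair  = alpha^2 / (alpha^2 + beta^2 + sigma^2)   (homotopic pairs)
    r_intra = beta^2  / (alpha^2 + beta^2 + sigma^2)   (same-side pairs)

and roughly zero for non-homotopic cross-side pairs.  Group effects are
injected by shifting the pair-latent weight inside a target region, so
the induced change in the asymmetry score is (approximately) a chosen
Fisher-z shift.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .io_core import (
    BoldDataset,
    BrainMask,
    MotionTrace,
    PasymError,
    SubjectTable,
    write_bold,
    write_mask,
    write_motion,
    write_subject_table,
)
from .pas import HemisphereLabeling, label_hemispheres
from .preprocess import ConfoundMatrix, build_confounds, framewise_displacement

#: per-group (mean, sd) defaults for the clinical-score generator
CLINICAL_DEFAULTS = {
    "age": {"GI_MDD": (30.86, 6.84), "NGI_MDD": (30.29, 8.05), "HC": (30.14, 5.00)},
    "education": {"GI_MDD": (14.51, 3.28), "NGI_MDD": (12.94, 3.46), "HC": (14.61, 2.69)},
    "illness_duration": {"GI_MDD": (6.23, 4.63), "NGI_MDD": (6.94, 3.98), "HC": None},
    "hrsd17_total": {"GI_MDD": (22.69, 3.41), "NGI_MDD": (20.18, 2.67), "HC": (0.89, 0.88)},
    "anxiety_somatization": {"GI_MDD": (7.31, 1.92), "NGI_MDD": (6.41, 1.66), "HC": (0.39, 0.57)},
    "weight_loss": {"GI_MDD": (0.80, 0.83), "NGI_MDD": (0.06, 0.24), "HC": (0.0, 0.0)},
    "cognitive_disturbance": {"GI_MDD": (3.71, 1.78), "NGI_MDD": (3.41, 1.50), "HC": (0.0, 0.0)},
    "retardation": {"GI_MDD": (6.40, 1.42), "NGI_MDD": (6.76, 1.56), "HC": (0.18, 0.39)},
    "sleep_disturbance": {"GI_MDD": (4.46, 1.42), "NGI_MDD": (3.53, 1.28), "HC": (0.32, 0.55)},
}

#: per-group probability that a subject is male
MALE_FRACTION = {"GI_MDD": 13 / 35, "NGI_MDD": 6 / 17, "HC": 14 / 28}

_Z_MIN, _Z_MAX = 0.02, 2.5


@dataclass
class SimDesign:
    """Everything the generator needs; all randomness flows from ``seed``."""

    shape: tuple = (10, 5, 4)
    voxel_size_mm: float = 3.0
    n_timepoints: int = 150
    tr_seconds: float = 2.0
    alpha_pair: float = np.sqrt(0.5)
    beta_hemi: float = 0.5
    sigma_noise: float = 0.5
    n_gi: int = 35
    n_ngi: int = 17
    n_hc: int = 28
    region_size: int = 0  # 0 = no injected effect
    effect_group: str = "GI_MDD"
    delta_pas_target: float = 0.0  # Fisher-z shift applied to region pairs
    pas_subject_sd: float = 0.0  # between-subject SD of the region z level
    motion_step_mm: float = 0.02
    motion_step_rad: float = 2e-4
    motion_bound_mm: float = 1.0
    motion_bound_rad: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.alpha_pair**2 + self.beta_hemi**2 + self.sigma_noise**2 <= 0:
            raise PasymError("at least one variance component must be positive")
        for n in (self.n_gi, self.n_ngi):
            if n < 2:
                raise PasymError("group sizes must be >= 2")
        if self.n_hc not in (0,) and self.n_hc < 2:
            raise PasymError("n_hc must be 0 or >= 2")

    @property
    def total_var(self) -> float:
        return self.alpha_pair**2 + self.beta_hemi**2 + self.sigma_noise**2

    @property
    def r_pair(self) -> float:
        return self.alpha_pair**2 / self.total_var

    @property
    def r_intra(self) -> float:
        return self.beta_hemi**2 / self.total_var

    def group_sizes(self) -> dict:
        return {"GI_MDD": self.n_gi, "NGI_MDD": self.n_ngi, "HC": self.n_hc}


@dataclass
class Cohort:
    """In-memory result of :func:`simulate_cohort`."""

    design: SimDesign
    mask: BrainMask
    labeling: HemisphereLabeling
    subjects: SubjectTable
    bolds: list
    motions: list
    confounds: list
    region_index: np.ndarray  # in-mask voxel indices carrying the effect
    deltas: np.ndarray  # per-subject realized region z shift


def make_mask(design: SimDesign) -> BrainMask:
    """Full-box mask whose world x axis is centered on 0.

    An even first dimension leaves no voxel on the midline plane.
    """
    vs = design.voxel_size_mm
    affine = np.diag([vs, vs, vs, 1.0])
    affine[:3, 3] = [-vs * (design.shape[0] - 1) / 2.0, 0.0, 0.0]
    return BrainMask(np.ones(design.shape, dtype=bool), affine)


def default_region(labeling: HemisphereLabeling, size: int) -> np.ndarray:
    """A mirror-symmetric region: the first size//2 left voxels that have a
    partner, plus their mirrors."""
    if size % 2:
        raise PasymError("region size must be even (pairs span both hemispheres)")
    left = [
        i
        for i in range(labeling.n_voxels)
        if labeling.side[i] == -1 and labeling.mirror_index[i] >= 0
    ]
    if len(left) < size // 2:
        raise PasymError("grid too small to host the requested region")
    chosen = left[: size // 2]
    return np.array(sorted(chosen + [int(labeling.mirror_index[i]) for i in chosen]))


def _pair_ids(labeling: HemisphereLabeling) -> np.ndarray:
    """A shared latent id per homotopic pair; unpaired voxels get their own."""
    ids = np.full(labeling.n_voxels, -1, dtype=np.int64)
    nxt = 0
    for i in range(labeling.n_voxels):
        if ids[i] >= 0:
            continue
        j = labeling.mirror_index[i]
        ids[i] = nxt
        if j >= 0:
            ids[j] = nxt
        nxt += 1
    return ids


def _bounded_walk(rng, n, step, bound, k) -> np.ndarray:
    walk = np.cumsum(rng.normal(0.0, step, (n, k)), axis=0)
    return np.clip(walk, -bound, bound)


def simulate_motion(design: SimDesign, subject_id: str, rng) -> MotionTrace:
    t = design.n_timepoints
    trans = _bounded_walk(rng, t, design.motion_step_mm, design.motion_bound_mm, 3)
    rot = _bounded_walk(rng, t, design.motion_step_rad, design.motion_bound_rad, 3)
    return MotionTrace(subject_id, np.hstack([trans, rot]))


def simulate_bold(
    design: SimDesign,
    subject_id: str,
    rng=None,
    labeling: HemisphereLabeling | None = None,
    alpha: np.ndarray | None = None,
) -> tuple[BoldDataset, MotionTrace, ConfoundMatrix]:
    """One subject's BOLD matrix plus a motion trace and confound matrix.

    ``alpha`` optionally overrides the pair-latent weight per voxel
    (used for injected regional effects); partners should share a value.
    """
    if rng is None:
        rng = np.random.default_rng(design.seed)
    mask = make_mask(design)
    if labeling is None:
        labeling = label_hemispheres(mask)
    v = labeling.n_voxels
    t = design.n_timepoints
    if alpha is None:
        alpha = np.full(v, design.alpha_pair)
    alpha = np.asarray(alpha, dtype=float)

    pair_ids = _pair_ids(labeling)
    s_pair = rng.normal(size=(pair_ids.max() + 1, t))
    s_hemi = rng.normal(size=(2, t))
    noise = rng.normal(size=(v, t))
    hemi_row = (labeling.side > 0).astype(int)  # excluded voxels borrow the left latent
    hemi = np.where(labeling.side == 0, 0.0, design.beta_hemi)
    data = (
        alpha[:, None] * s_pair[pair_ids]
        + hemi[:, None] * s_hemi[hemi_row]
        + design.sigma_noise * noise
    ).T  # (T, V)

    bold = BoldDataset(
        subject_id=subject_id,
        data=data,
        voxel_coords=mask.voxel_coords,
        affine=mask.affine,
        tr_seconds=design.tr_seconds,
    )
    motion = simulate_motion(design, subject_id, rng)
    nuisance = pd.DataFrame(
        {"csf": rng.normal(size=t), "wm": rng.normal(size=t)}
    )
    confounds = build_confounds(motion, nuisance)
    return bold, motion, confounds


def _truncated_normal(rng, mean, sd, n) -> np.ndarray:
    if sd <= 0:
        return np.full(n, float(mean))
    a = (0.0 - mean) / sd
    return stats.truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=n, random_state=rng)


def _region_alpha(design: SimDesign, region: np.ndarray, delta: float, n_voxels: int) -> np.ndarray:
    """Pair-latent weights realizing a Fisher-z shift ``delta`` on region pairs."""
    alpha = np.full(n_voxels, design.alpha_pair)
    if region.size == 0:
        return alpha
    base_z = np.arctanh(design.r_pair) if design.r_pair > 0 else _Z_MIN
    z = float(np.clip(base_z + delta, _Z_MIN, _Z_MAX))
    r = np.tanh(z)
    other = design.beta_hemi**2 + design.sigma_noise**2
    alpha[region] = np.sqrt(r * other / (1.0 - r))
    return alpha


def simulate_cohort(design: SimDesign) -> Cohort:
    """A full group-structured cohort: BOLD + motion per subject, and a
    subject table with covariates and clinical scores.

    When a region effect is configured, every subject's region z level is
    jittered (between-subject SD ``pas_subject_sd``) and subjects of
    ``effect_group`` additionally receive the mean shift
    ``delta_pas_target``; the GI-symptom item is a noisy monotone
    function of each patient's realized shift so association recovery is
    testable.
    """
    ss = np.random.SeedSequence(design.seed)
    table_rng = np.random.default_rng(ss.spawn(1)[0])
    mask = make_mask(design)
    labeling = label_hemispheres(mask)
    region = (
        default_region(labeling, design.region_size)
        if design.region_size > 0
        else np.array([], dtype=np.int64)
    )

    groups, ids = [], []
    for g, n in design.group_sizes().items():
        groups += [g] * n
        ids += [f"sub-{len(ids) + k + 1:03d}" for k in range(n)]
    n_sub = len(ids)
    group_arr = np.array(groups)

    deltas = np.zeros(n_sub)
    if region.size:
        deltas = table_rng.normal(0.0, design.pas_subject_sd, n_sub)
        deltas[group_arr == design.effect_group] += design.delta_pas_target

    subject_seeds = ss.spawn(n_sub)
    bolds, motions, confounds = [], [], []
    for i, sid in enumerate(ids):
        rng = np.random.default_rng(subject_seeds[i])
        alpha = _region_alpha(design, region, deltas[i], labeling.n_voxels)
        bold, motion, conf = simulate_bold(design, sid, rng, labeling, alpha)
        bolds.append(bold)
        motions.append(motion)
        confounds.append(conf)

    rows = {"subject_id": ids, "group": groups}
    for var, per_group in CLINICAL_DEFAULTS.items():
        vals = np.full(n_sub, np.nan)
        for g in np.unique(group_arr):
            params = per_group.get(g)
            sel = group_arr == g
            if params is None:
                continue
            vals[sel] = _truncated_normal(table_rng, *params, int(sel.sum()))
        rows[var] = vals
    rows["gender"] = [
        "male" if table_rng.random() < MALE_FRACTION[g] else "female" for g in groups
    ]
    rows["mean_fd"] = [
        float(framewise_displacement(m).mean()) for m in motions
    ]

    gi_item = np.zeros(n_sub)
    is_gi = group_arr == "GI_MDD"
    if is_gi.any():
        latent = deltas[is_gi] + table_rng.normal(0.0, 0.1, int(is_gi.sum()))
        # ordinal severity 1..3 by latent tertile: monotone in the injected shift
        ranks = stats.rankdata(latent, method="average") / (is_gi.sum() + 1)
        gi_item[is_gi] = 1 + np.floor(ranks * 3).clip(0, 2)
    rows["gi_item"] = gi_item

    df = pd.DataFrame(rows)
    order = ["subject_id", "group", "age", "gender", "education", "mean_fd",
             "illness_duration", "hrsd17_total", "anxiety_somatization",
             "weight_loss", "cognitive_disturbance", "retardation",
             "sleep_disturbance", "gi_item"]
    table = SubjectTable(df[order])
    return Cohort(design, mask, labeling, table, bolds, motions, confounds,
                  region, deltas)


def write_cohort(cohort: Cohort, out_dir) -> pd.DataFrame:
    """Write the cohort as plain files and return a manifest table."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_mask(cohort.mask, out / "mask.nii.gz")
    write_subject_table(cohort.subjects, out / "subjects.tsv")
    rows = []
    for bold, motion, conf in zip(cohort.bolds, cohort.motions, cohort.confounds):
        sid = bold.subject_id
        bold_path = out / f"{sid}_bold.nii.gz"
        motion_path = out / f"{sid}_motion.tsv"
        nuis_path = out / f"{sid}_nuisance.tsv"
        write_bold(bold, cohort.mask, bold_path)
        write_motion(motion, motion_path)
        nuis = pd.DataFrame(conf.values[:, -2:], columns=["csf", "wm"])
        nuis.to_csv(nuis_path, sep="\t", index=False)
        rows.append({"subject_id": sid, "bold": bold_path.name,
                     "motion": motion_path.name, "nuisance": nuis_path.name})
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out / "manifest.tsv", sep="\t", index=False)
    if cohort.region_index.size:
        np.savetxt(out / "region_voxels.txt", cohort.region_index, fmt="%d")
    return manifest
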