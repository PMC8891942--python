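"""Temporal preprocessing of spatially normalized BOLD data.

Implements the fixed stage order: nuisance regression, linear detrending
plus band-pass filtering, then motion scrubbing.  Spatial steps
(realignment, normalization, smoothing) are expected to have been done
by standard external tools.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_core import BoldDataset, MotionTrace, PasymError, RunConfig, ValidationError

#: rotation-to-arc-length radius used by the displacement convention
DEFAULT_ROTATION_RADIUS_MM = 50.0

NUISANCE_COLUMNS = ("csf", "wm")


@dataclass
class ConfoundMatrix:
    """Time-by-regressor nuisance matrix with column names."""

    values: np.ndarray  # (T, K)
    names: list

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("confound matrix must be 2-D")
        if self.values.shape[1] != len(self.names):
            raise ValidationError("confound names must match column count")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]


def framewise_displacement(
    motion: MotionTrace, rotation_radius_mm: float = DEFAULT_ROTATION_RADIUS_MM
) -> np.ndarray:
    """Per-frame head displacement in mm.

    Sum of absolute backward differences of the six parameters, with
    rotations (radians) converted to arc length on a sphere of
    ``rotation_radius_mm``.  The first frame is defined as 0.
    """
    if motion.n_frames < 2:
        raise PasymError("framewise displacement needs at least 2 time points")
    d = np.abs(np.diff(motion.params, axis=0))
    fd = d[:, :3].sum(axis=1) + rotation_radius_mm * d[:, 3:].sum(axis=1)
    return np.concatenate([[0.0], fd])


def exclude_subject_by_motion(
    motion: MotionTrace,
    max_translation_mm: float = 2.0,
    max_rotation_deg: float = 2.0,
) -> bool:
    """True if the subject exceeds the translation/rotation limits.

    Strict inequalities: a maximum of exactly the limit is kept.
    """
    if max_translation_mm <= 0 or max_rotation_deg <= 0:
        raise ValidationError("motion exclusion thresholds must be positive")
    max_trans = np.abs(motion.translations).max()
    max_rot_deg = np.degrees(np.abs(motion.rotations).max())
    return bool(max_trans > max_translation_mm or max_rot_deg > max_rotation_deg)


def friston24(motion: MotionTrace) -> ConfoundMatrix:
    """24-regressor motion model: parameters, one-frame lags, and both squared."""
    if motion.n_frames < 2:
        raise PasymError("Friston-24 needs at least 2 time points")
    p = motion.params
    lag = np.zeros_like(p)
    lag[1:] = p[:-1]
    values = np.hstack([p, lag, p**2, lag**2])
    base = ["trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z"]
    names = base + [f"{n}_lag" for n in base] + [f"{n}_sq" for n in base] + [
        f"{n}_lag_sq" for n in base
    ]
    return ConfoundMatrix(values, names)


def build_confounds(motion: MotionTrace, nuisance: pd.DataFrame | None = None) -> ConfoundMatrix:
    """Friston-24 motion terms plus mean CSF and WM signal columns.

    ``nuisance`` is a table with ``csf`` and ``wm`` columns (computed
    upstream); it may be None when tissue signals are unavailable.
    """
    conf = friston24(motion)
    if nuisance is None:
        return conf
    missing = [c for c in NUISANCE_COLUMNS if c not in nuisance.columns]
    if missing:
        raise ValidationError(f"nuisance table missing column(s): {', '.join(missing)}")
    if len(nuisance) != conf.n_frames:
        raise PasymError("nuisance signal length does not match motion trace")
    values = np.hstack([conf.values, nuisance[list(NUISANCE_COLUMNS)].to_numpy(float)])
    return ConfoundMatrix(values, conf.names + list(NUISANCE_COLUMNS))


def regress_confounds(bold: BoldDataset, confounds: ConfoundMatrix) -> BoldDataset:
    """Replace each voxel series by its residual against [intercept | confounds].

    Uses a minimum-norm least-squares solution, so rank-deficient designs
    (e.g. constant or duplicated regressors) are handled gracefully.
    """
    if confounds.n_frames != bold.n_frames:
        raise PasymError(
            f"confound rows ({confounds.n_frames}) != BOLD frames ({bold.n_frames})"
        )
    design = np.column_stack([np.ones(bold.n_frames), confounds.values])
    beta, *_ = np.linalg.lstsq(design, bold.data, rcond=None)
    resid = bold.data - design @ beta
    return bold.replace(data=resid)


def detrend_and_bandpass(bold: BoldDataset, low_hz: float, high_hz: float) -> BoldDataset:
    """Remove each voxel's linear trend, then keep only [low, high] Hz.

    Filtering is a hard Fourier-domain mask on the real FFT of the full
    (unscrubbed) series; components outside the band, including DC, are
    zeroed.
    """
    nyquist = 1.0 / (2.0 * bold.tr_seconds)
    if not 0 < low_hz < high_hz < nyquist:
        raise PasymError(
            f"band ({low_hz}, {high_hz}) Hz must satisfy 0 < low < high < Nyquist ({nyquist})"
        )
    t = np.arange(bold.n_frames, dtype=float)
    t -= t.mean()
    # least-squares line removal per voxel
    slope = (t @ bold.data) / (t @ t)
    detrended = bold.data - bold.data.mean(axis=0) - np.outer(t, slope)
    spec = np.fft.rfft(detrended, axis=0)
    freqs = np.fft.rfftfreq(bold.n_frames, d=bold.tr_seconds)
    keep = (freqs >= low_hz) & (freqs <= high_hz)
    spec[~keep] = 0
    filtered = np.fft.irfft(spec, n=bold.n_frames, axis=0)
    return bold.replace(data=filtered)


def scrub(bold: BoldDataset, fd: np.ndarray, threshold_mm: float) -> BoldDataset:
    """Mark frames with FD above threshold as censored.

    Censored frames are deleted (never interpolated) by downstream
    correlation code.  Having fewer than 3 retained frames is only an
    error once a correlation is requested.
    """
    fd = np.asarray(fd, dtype=float)
    if fd.shape != (bold.n_frames,):
        raise PasymError("FD series length does not match BOLD frames")
    keep = bold.frame_keep_mask & (fd <= threshold_mm)
    return bold.replace(frame_keep_mask=keep)


def qc_summary(motion: MotionTrace, fd: np.ndarray, keep_mask: np.ndarray) -> dict:
    """Per-subject quality-control numbers for the QC table."""
    return {
        "subject_id": motion.subject_id,
        "max_translation_mm": float(np.abs(motion.translations).max()),
        "max_rotation_deg": float(np.degrees(np.abs(motion.rotations).max())),
        "mean_fd": float(np.mean(fd)),
        "n_frames": int(len(fd)),
        "n_retained": int(np.sum(keep_mask)),
    }


def preprocess_subject(
    bold: BoldDataset,
    motion: MotionTrace,
    nuisance: pd.DataFrame | None,
    config: RunConfig,
) -> tuple[BoldDataset, dict]:
    """Full temporal chain: regression -> detrend+bandpass -> scrubbing."""
    if motion.n_frames != bold.n_frames:
        raise PasymError(
            f"{bold.subject_id}: motion rows ({motion.n_frames}) != BOLD frames ({bold.n_frames})"
        )
    confounds = build_confounds(motion, nuisance)
    out = regress_confounds(bold, confounds)
    out = detrend_and_bandpass(out, *config.bandpass_hz)
    fd = framewise_displacement(motion)
    out = scrub(out, fd, config.fd_scrub_threshold_mm)
    return out, qc_summary(motion, fd, out.frame_keep_mask)
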