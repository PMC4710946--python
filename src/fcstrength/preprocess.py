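"""Temporal cleaning of BOLD series and head-motion summarization.

Implements the non-spatial preprocessing chain used before connectivity
analysis: per-voxel linear detrend, ideal (FFT-mask) band-pass filtering to
the low-frequency BOLD band, least-squares nuisance regression (six motion
parameters plus global / white-matter / CSF mean signals), framewise
displacement in the sum-of-absolute-derivatives form, and construction of
the group gray-matter analysis mask from averaged probability maps.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import scipy.linalg

from .cohort import Bold4D, MotionTrace

__all__ = [
    "GMMask",
    "FDSeries",
    "temporal_clean",
    "regress_nuisance",
    "extract_confound_series",
    "framewise_displacement",
    "group_gm_mask",
    "clean_subject",
]


@dataclass
class GMMask:
    """Boolean analysis mask plus the probability map it was cut from."""

    include: np.ndarray
    source_probability: np.ndarray

    def __post_init__(self) -> None:
        self.include = np.asarray(self.include, dtype=bool)
        self.source_probability = np.asarray(self.source_probability, dtype=float)
        if self.include.shape != self.source_probability.shape:
            raise ValueError("mask and probability map shapes differ")

    @property
    def n_voxels(self) -> int:
        return int(self.include.sum())


@dataclass
class FDSeries:
    """Per-frame framewise displacement (mm); first frame is defined as 0."""

    fd_mm: np.ndarray
    mean_fd_mm: float

    def __post_init__(self) -> None:
        self.fd_mm = np.asarray(self.fd_mm, dtype=float)
        if (self.fd_mm < 0).any():
            raise ValueError("FD must be nonnegative")


def temporal_clean(bold: Bold4D, low_hz: float = 0.01, high_hz: float = 0.08) -> Bold4D:
    """Linear detrend then ideal band-pass filter each voxel series.

    The filter zeroes every discrete frequency bin outside ``[low_hz,
    high_hz]`` (inclusive); the DC bin is always removed by the detrend.
    Raises if the band is empty at this series length or if ``high_hz``
    reaches the Nyquist frequency.
    """
    t = bold.n_timepoints
    nyquist = 1.0 / (2.0 * bold.tr_s)
    if not 0 <= low_hz < high_hz:
        raise ValueError("need 0 <= low_hz < high_hz")
    if high_hz >= nyquist:
        raise ValueError(f"high_hz {high_hz} must be below Nyquist {nyquist}")
    freqs = np.fft.rfftfreq(t, d=bold.tr_s)
    keep = (freqs >= low_hz) & (freqs <= high_hz)
    if not keep.any():
        raise ValueError(
            f"series of length {t} has no frequency bin in [{low_hz}, {high_hz}] Hz"
        )

    flat = bold.data.reshape(-1, t).astype(np.float64)
    # linear detrend: project out [1, t] per voxel
    time = np.arange(t, dtype=np.float64)
    design = np.column_stack([np.ones(t), time])
    q, _ = np.linalg.qr(design)
    detrended = flat - (flat @ q) @ q.T

    spec = np.fft.rfft(detrended, axis=1)
    spec[:, ~keep] = 0.0
    cleaned = np.fft.irfft(spec, n=t, axis=1)
    return Bold4D(cleaned.reshape(bold.data.shape), bold.voxel_size_mm, bold.tr_s)


def _collinear_columns(design: np.ndarray, names: Sequence[str]) -> list[str]:
    _, r, piv = scipy.linalg.qr(design, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(design.shape) * np.finfo(float).eps
    rank = int((diag > tol).sum())
    return [names[j] for j in piv[rank:]]


def regress_nuisance(bold: Bold4D, regressors: np.ndarray,
                     names: Sequence[str] | None = None) -> Bold4D:
    """Residualize every voxel series on ``[intercept | regressors]``.

    Raises on a rank-deficient design, naming the dependent columns.
    """
    t = bold.n_timepoints
    regressors = np.asarray(regressors, dtype=np.float64)
    if regressors.ndim != 2 or regressors.shape[0] != t:
        raise ValueError(f"regressors must be {t} x k, got {regressors.shape}")
    k = regressors.shape[1]
    if names is None:
        names = [f"regressor_{j}" for j in range(k)]
    design = np.column_stack([np.ones(t), regressors])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        bad = _collinear_columns(design, ["intercept", *names])
        raise ValueError(f"rank-deficient nuisance design; collinear columns: {bad}")
    q, _ = np.linalg.qr(design)
    flat = bold.data.reshape(-1, t).astype(np.float64)
    resid = flat - (flat @ q) @ q.T
    return Bold4D(resid.reshape(bold.data.shape), bold.voxel_size_mm, bold.tr_s)


def extract_confound_series(bold: Bold4D, masks: Mapping[str, np.ndarray]) -> np.ndarray:
    """t x 3 matrix of mean signals over the global, WM and CSF masks (that order)."""
    columns = []
    for key in ("global", "wm", "csf"):
        mask = np.asarray(masks[key])
        if mask.dtype != bool:
            mask = mask.astype(bool)
        if not mask.any():
            raise ValueError(f"empty {key!r} mask")
        columns.append(bold.data[mask].mean(axis=0))
    return np.column_stack(columns)


def framewise_displacement(motion: MotionTrace, head_radius_mm: float = 50.0) -> FDSeries:
    """Framewise displacement: sum of absolute frame-to-frame parameter changes.

    ``FD_i = sum |dT_i| + r * sum |dR_i]`` with rotations converted to arc
    length at an assumed ``head_radius_mm`` sphere; the first frame is 0.
    """
    if motion.n_frames < 2:
        raise ValueError("need at least 2 frames to compute FD")
    dt = np.abs(np.diff(motion.translations_mm, axis=0)).sum(axis=1)
    dr = np.abs(np.diff(motion.rotations_rad, axis=0)).sum(axis=1)
    fd = np.concatenate([[0.0], dt + head_radius_mm * dr])
    return FDSeries(fd_mm=fd, mean_fd_mm=float(fd.mean()))


def group_gm_mask(gm_maps: Sequence[np.ndarray], cutoff: float = 0.2) -> GMMask:
    """Threshold the elementwise mean of all subjects' GM probability maps.

    A voxel is included iff its mean probability is >= ``cutoff`` (boundary
    inclusive).
    """
    if len(gm_maps) == 0:
        raise ValueError("need at least one GM probability map")
    maps = [np.asarray(m, dtype=float) for m in gm_maps]
    shape = maps[0].shape
    if any(m.shape != shape for m in maps):
        raise ValueError("all GM maps must share dimensions")
    stacked = np.stack(maps)
    if stacked.min() < 0 or stacked.max() > 1:
        raise ValueError("GM probabilities must lie in [0, 1]")
    mean_map = stacked.mean(axis=0)
    return GMMask(include=mean_map >= cutoff, source_probability=mean_map)


def clean_subject(
    bold: Bold4D,
    motion: MotionTrace,
    masks: Mapping[str, np.ndarray],
    low_hz: float = 0.01,
    high_hz: float = 0.08,
    gsr: bool = True,
) -> Bold4D:
    """Standard chain: detrend -> band-pass -> nuisance regression.

    Nuisance regressors are the six motion parameters plus WM and CSF mean
    signals, and the global mean signal when ``gsr`` is on.  The global mean
    is taken over the gray-matter analysis mask (``masks['global']``).
    Confound series are extracted from the band-passed data so regressors
    and data live in the same band.
    """
    cleaned = temporal_clean(bold, low_hz, high_hz)
    confounds = extract_confound_series(cleaned, masks)
    names = ["global", "wm", "csf"]
    if not gsr:
        confounds = confounds[:, 1:]
        names = names[1:]
    regressors = np.column_stack([motion.as_matrix(), confounds])
    names = ["tx", "ty", "tz", "rx", "ry", "rz", *names]
    return regress_nuisance(cleaned, regressors, names=names)
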