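"""Voxelwise functional connectivity strength and seed-based connectivity.

Functional connectivity strength (FCS) is a weighted degree-centrality
measure: for every gray-matter voxel, the Pearson correlations with all
other gray-matter voxels are computed, correlations above a threshold
(default r > 0.2, strict) are Fisher r-to-z transformed, and their sum is
the voxel's FCS.  Seed-based maps correlate every gray-matter voxel with
the mean time course of a seed region and store the Fisher-z values.

Correlations are computed in row blocks so peak memory stays
O(block_size * n_voxels) rather than O(n_voxels**2).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .cohort import Bold4D
from .preprocess import GMMask

logger = logging.getLogger(__name__)

__all__ = [
    "FcsMap",
    "SeedFcMap",
    "fisher_z",
    "compute_fcs",
    "seed_timecourse",
    "seed_fc_map",
    "MAX_ABS_R",
]

#: correlations are clipped to +/- this value before arctanh so exact
#: duplicates (r = 1) map to a finite, documented maximum z of ~8.4.
MAX_ABS_R = 1.0 - 1e-7
MAX_ABS_Z = float(np.arctanh(MAX_ABS_R))


def fisher_z(r, warn: bool = True):
    """Fisher r-to-z transform, arctanh(r), with |r| clipped below 1.

    Scalar in, scalar out; arrays transform elementwise.  Values at or
    beyond +/-1 are clipped to ``MAX_ABS_R`` and counted in a logged
    warning.
    """
    arr = np.asarray(r, dtype=float)
    n_clipped = int((np.abs(arr) >= 1.0).sum())
    if n_clipped and warn:
        logger.warning("fisher_z: clipped %d correlation(s) with |r| >= 1", n_clipped)
    z = np.arctanh(np.clip(arr, -MAX_ABS_R, MAX_ABS_R))
    return float(z) if np.isscalar(r) else z


@dataclass
class FcsMap:
    """Per-voxel FCS values on a gray-matter mask (zero outside it)."""

    values: np.ndarray
    r_threshold: float
    mask: np.ndarray
    mode: str = "zsum"
    n_clipped: int = 0
    n_dropped_voxels: int = 0

    def masked_values(self) -> np.ndarray:
        return self.values[self.mask]


@dataclass
class SeedFcMap:
    """Fisher-z correlation of every mask voxel with a seed time course."""

    values: np.ndarray
    seed_name: str
    mask: np.ndarray
    positive_mask: np.ndarray | None = None


def _standardize_series(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Rows scaled so that X @ X.T is the Pearson correlation matrix.

    Returns the scaled matrix and a boolean row validity flag (False for
    zero-variance rows, which are left as zeros).
    """
    x = np.asarray(x, dtype=np.float64)
    centered = x - x.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    valid = norms > 0
    scaled = np.zeros_like(centered)
    scaled[valid] = centered[valid] / norms[valid, None]
    return scaled, valid


def compute_fcs(
    bold: Bold4D,
    mask: GMMask,
    r_threshold: float = 0.2,
    mode: str = "zsum",
    block_size: int = 1024,
) -> FcsMap:
    """Whole-mask FCS map of one subject.

    ``mode`` selects what is summed over connections with r strictly above
    the threshold: ``zsum`` (Fisher-z values, default), ``rsum`` (raw r), or
    ``count`` (binary degree).  Zero-variance voxels inside the mask are
    dropped with a warning; the self-connection is always excluded.
    """
    if mode not in ("zsum", "rsum", "count"):
        raise ValueError(f"unknown FCS mode {mode!r}")
    if not 0 < r_threshold < 1:
        raise ValueError("r_threshold must lie in (0, 1)")
    include = mask.include
    if include.shape != bold.grid_dims:
        raise ValueError("mask does not match BOLD grid")
    idx = np.argwhere(include)
    if len(idx) < 2:
        raise ValueError("FCS needs at least 2 mask voxels")

    series = bold.data[include]  # (V, T), voxel order = C order of the grid
    scaled, valid = _standardize_series(series)
    n_dropped = int((~valid).sum())
    if n_dropped:
        logger.warning("compute_fcs: dropped %d zero-variance voxel(s)", n_dropped)
        idx = idx[valid]
        scaled = scaled[valid]
    n = scaled.shape[0]
    if n < 2:
        raise ValueError("fewer than 2 nonconstant voxels in mask")

    fcs = np.zeros(n)
    n_clipped = 0
    for start in range(0, n, block_size):
        stop = min(start + block_size, n)
        r_block = scaled[start:stop] @ scaled.T  # (b, n)
        rows = np.arange(start, stop)
        r_block[rows - start, rows] = 0.0  # exclude self-connection
        supra = r_block > r_threshold
        n_clipped += int((np.abs(r_block[supra]) >= 1.0).sum())
        if mode == "count":
            fcs[start:stop] = supra.sum(axis=1)
        elif mode == "rsum":
            fcs[start:stop] = np.where(supra, r_block, 0.0).sum(axis=1)
        else:
            z = np.arctanh(np.clip(r_block, -MAX_ABS_R, MAX_ABS_R))
            fcs[start:stop] = np.where(supra, z, 0.0).sum(axis=1)
    if n_clipped:
        logger.warning("compute_fcs: clipped %d correlation(s) with |r| >= 1", n_clipped)

    values = np.zeros(bold.grid_dims)
    values[idx[:, 0], idx[:, 1], idx[:, 2]] = fcs
    return FcsMap(
        values=values,
        r_threshold=r_threshold,
        mask=include,
        mode=mode,
        n_clipped=n_clipped,
        n_dropped_voxels=n_dropped,
    )


def pairwise_correlations(bold: Bold4D, mask: GMMask) -> tuple[np.ndarray, np.ndarray]:
    """Full correlation matrix over mask voxels plus their index array.

    Intended for threshold sweeps on desk-scale masks, where one correlation
    pass can feed several FCS thresholds (see :func:`fcs_from_correlations`).
    """
    include = mask.include
    idx = np.argwhere(include)
    scaled, valid = _standardize_series(bold.data[include])
    idx = idx[valid]
    scaled = scaled[valid]
    r = scaled @ scaled.T
    np.fill_diagonal(r, 0.0)
    return r, idx


def fcs_from_correlations(
    r: np.ndarray,
    idx: np.ndarray,
    grid_dims: tuple[int, int, int],
    mask: np.ndarray,
    r_threshold: float = 0.2,
    mode: str = "zsum",
) -> FcsMap:
    """FCS map from a precomputed correlation matrix (diagonal already zero)."""
    supra = r > r_threshold
    if mode == "count":
        fcs = supra.sum(axis=1).astype(float)
    elif mode == "rsum":
        fcs = np.where(supra, r, 0.0).sum(axis=1)
    elif mode == "zsum":
        fcs = np.where(supra, np.arctanh(np.clip(r, -MAX_ABS_R, MAX_ABS_R)), 0.0).sum(axis=1)
    else:
        raise ValueError(f"unknown FCS mode {mode!r}")
    values = np.zeros(grid_dims)
    values[idx[:, 0], idx[:, 1], idx[:, 2]] = fcs
    return FcsMap(values=values, r_threshold=r_threshold, mask=np.asarray(mask, bool), mode=mode)


def seed_timecourse(bold: Bold4D, seed_mask: np.ndarray) -> np.ndarray:
    """Mean time course over the seed voxels."""
    seed_mask = np.asarray(seed_mask, dtype=bool)
    if seed_mask.shape != bold.grid_dims:
        raise ValueError("seed mask does not match BOLD grid")
    if not seed_mask.any():
        raise ValueError("empty seed mask")
    return bold.data[seed_mask].mean(axis=0)


def seed_fc_map(
    bold: Bold4D,
    seed_series: np.ndarray,
    mask: GMMask,
    seed_name: str = "seed",
    positive_only: bool = True,
) -> SeedFcMap:
    """Fisher-z map of correlations between every mask voxel and the seed.

    When ``positive_only`` is set the returned ``positive_mask`` marks mask
    voxels with z > 0, the analysis restriction used for seed-based group
    statistics (negative connections are not analyzed).
    """
    seed_series = np.asarray(seed_series, dtype=np.float64)
    if seed_series.shape != (bold.n_timepoints,):
        raise ValueError("seed series length must equal the number of frames")
    seed_centered = seed_series - seed_series.mean()
    seed_norm = np.linalg.norm(seed_centered)
    if seed_norm == 0:
        raise ValueError("seed series has zero variance")
    include = mask.include
    scaled, valid = _standardize_series(bold.data[include])
    r = scaled @ (seed_centered / seed_norm)
    r[~valid] = 0.0
    z = np.arctanh(np.clip(r, -MAX_ABS_R, MAX_ABS_R))
    values = np.zeros(bold.grid_dims)
    values[include] = z
    positive = np.zeros(bold.grid_dims, dtype=bool)
    if positive_only:
        positive[include] = z > 0
    return SeedFcMap(values=values, seed_name=seed_name, mask=include,
                     positive_mask=positive if positive_only else None)
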