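"""Monte-Carlo cluster-extent correction and cluster labeling.

The extent threshold is estimated AlphaSim-style: on each iteration an iid
standard Gaussian field is drawn on the analysis mask, smoothed with a
Gaussian kernel of the requested FWHM, re-standardized within the mask,
thresholded two-tailed at the voxelwise p level, and the size of the
largest connected suprathreshold component is recorded.  The minimum
cluster extent for a corrected alpha is the smallest size k whose null
exceedance fraction is at most alpha.  Connectivity is 18 (face + edge) by
default; 6 and 26 are selectable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats

__all__ = [
    "ClusterThresholdEstimate",
    "ClusterTable",
    "estimate_cluster_extent_threshold",
    "extract_clusters",
    "fwe_calibration",
    "CONNECTIVITY_STRUCTURES",
]

CONNECTIVITY_STRUCTURES = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


@dataclass
class ClusterThresholdEstimate:
    min_extent_voxels: int
    min_extent_mm3: float
    voxel_p: float
    alpha: float
    fwhm_mm: float
    n_iterations: int
    connectivity: int
    null_max_sizes: np.ndarray

    def exceedance_fraction(self, k: int) -> float:
        """Fraction of null iterations whose largest cluster reached size k."""
        return float((self.null_max_sizes >= k).mean())


@dataclass
class ClusterTable:
    """Suprathreshold clusters sorted by size desc, ties by peak then index."""

    clusters: list[dict]

    def __len__(self) -> int:
        return len(self.clusters)

    def largest(self) -> dict | None:
        return self.clusters[0] if self.clusters else None

    def to_records(self) -> list[dict]:
        return [dict(c, peak_index=tuple(c["peak_index"])) for c in self.clusters]


def _null_field(
    rng: np.random.Generator,
    mask: np.ndarray,
    sigma_vox: float,
) -> np.ndarray:
    """Smoothed, mask-standardized Gaussian null field on the full grid."""
    field = rng.standard_normal(mask.shape)
    if sigma_vox > 0:
        field = ndimage.gaussian_filter(field, sigma=sigma_vox)
    vals = field[mask]
    sd = vals.std()
    if sd == 0:
        raise ValueError("degenerate null field")
    field = (field - vals.mean()) / sd
    return field


def _largest_cluster(supra: np.ndarray, structure: np.ndarray) -> int:
    labels, n = ndimage.label(supra, structure=structure)
    if n == 0:
        return 0
    return int(np.bincount(labels.ravel())[1:].max())


def _fwhm_to_sigma_vox(fwhm_mm: float, voxel_size_mm: float) -> float:
    return fwhm_mm / (voxel_size_mm * 2.0 * np.sqrt(2.0 * np.log(2.0)))


def estimate_cluster_extent_threshold(
    mask: np.ndarray,
    fwhm_mm: float = 4.0,
    voxel_p: float = 0.05,
    alpha: float = 0.05,
    n_iterations: int = 1000,
    connectivity: int = 18,
    seed: int | np.random.SeedSequence = 0,
    voxel_size_mm: float = 3.0,
) -> ClusterThresholdEstimate:
    """Minimum cluster extent whose null familywise rate is at most alpha."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    if not (0 < voxel_p < 1 and 0 < alpha <= 1):
        raise ValueError("voxel_p and alpha must lie in (0, 1]")
    if n_iterations < 100:
        raise ValueError("need at least 100 iterations")
    if alpha < 1.0 / n_iterations:
        raise ValueError(
            f"alpha {alpha} unresolvable with {n_iterations} iterations"
        )
    structure = CONNECTIVITY_STRUCTURES[connectivity]
    z_thr = stats.norm.isf(voxel_p / 2.0)  # two-tailed voxel threshold
    sigma = _fwhm_to_sigma_vox(fwhm_mm, voxel_size_mm)
    rng = np.random.default_rng(seed)

    max_sizes = np.empty(n_iterations, dtype=int)
    for i in range(n_iterations):
        field = _null_field(rng, mask, sigma)
        supra = mask & (np.abs(field) > z_thr)
        max_sizes[i] = _largest_cluster(supra, structure)
    max_sizes.sort()

    # smallest k with P(max null cluster >= k) <= alpha; the exceedance
    # fraction only changes at observed sizes + 1, so scan those candidates
    n = float(n_iterations)
    candidates = np.unique(np.concatenate([[1], max_sizes + 1]))
    k = int(candidates[-1])
    for cand in candidates:
        exceed = n_iterations - np.searchsorted(max_sizes, cand, side="left")
        if exceed / n <= alpha:
            k = int(cand)
            break
    return ClusterThresholdEstimate(
        min_extent_voxels=k,
        min_extent_mm3=k * voxel_size_mm**3,
        voxel_p=voxel_p,
        alpha=alpha,
        fwhm_mm=fwhm_mm,
        n_iterations=n_iterations,
        connectivity=connectivity,
        null_max_sizes=max_sizes,
    )


def extract_clusters(
    values: np.ndarray,
    stat_threshold: float,
    min_extent_voxels: int = 1,
    connectivity: int = 18,
    voxel_volume_mm3: float = 27.0,
    mask: np.ndarray | None = None,
) -> ClusterTable:
    """Connected components of voxels with ``values > stat_threshold``.

    Two-sided maps should be passed as ``np.abs(values)`` or as separate
    positive/negative calls.  Components smaller than
    ``min_extent_voxels`` are dropped; an empty table is a valid result.
    """
    values = np.asarray(values, dtype=float)
    if not np.isfinite(stat_threshold):
        raise ValueError("stat_threshold must be finite")
    supra = values > stat_threshold
    if mask is not None:
        supra &= np.asarray(mask, dtype=bool)
    structure = CONNECTIVITY_STRUCTURES[connectivity]
    labels, n = ndimage.label(supra, structure=structure)
    clusters = []
    for label_id in range(1, n + 1):
        where = labels == label_id
        size = int(where.sum())
        if size < min_extent_voxels:
            continue
        vals = np.where(where, values, -np.inf)
        peak_flat = int(np.argmax(vals))
        peak_index = np.unravel_index(peak_flat, values.shape)
        clusters.append(
            {
                "id": label_id,
                "size_voxels": size,
                "size_mm3": size * voxel_volume_mm3,
                "peak_value": float(values[peak_index]),
                "peak_index": tuple(int(v) for v in peak_index),
                "voxel_mask": where,
            }
        )
    clusters.sort(key=lambda c: (-c["size_voxels"], -c["peak_value"], c["peak_index"]))
    for new_id, c in enumerate(clusters, start=1):
        c["id"] = new_id
    return ClusterTable(clusters)


def fwe_calibration(
    mask: np.ndarray,
    fwhm_mm: float,
    voxel_p: float,
    threshold_estimate: ClusterThresholdEstimate,
    n_fresh: int = 1000,
    seed: int | np.random.SeedSequence = 1,
    voxel_size_mm: float = 3.0,
) -> float:
    """Observed familywise error of the extent threshold on fresh null fields.

    Returns the fraction of ``n_fresh`` independent null fields containing
    any suprathreshold cluster at least ``min_extent_voxels`` large; the
    seed must be independent of the estimation seed.
    """
    if n_fresh < 100:
        raise ValueError("need at least 100 fresh null fields")
    mask = np.asarray(mask, dtype=bool)
    structure = CONNECTIVITY_STRUCTURES[threshold_estimate.connectivity]
    z_thr = stats.norm.isf(voxel_p / 2.0)
    sigma = _fwhm_to_sigma_vox(fwhm_mm, voxel_size_mm)
    rng = np.random.default_rng(seed)
    k = threshold_estimate.min_extent_voxels
    hits = 0
    for _ in range(n_fresh):
        field = _null_field(rng, mask, sigma)
        supra = mask & (np.abs(field) > z_thr)
        if _largest_cluster(supra, structure) >= k:
            hits += 1
    return hits / n_fresh
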