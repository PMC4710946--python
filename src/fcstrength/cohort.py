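"""Synthetic resting-state cohorts with group-graded network coupling.

The generator emulates the statistical structure a whole-brain functional
connectivity strength (FCS) analysis of Alzheimer's conversion assumes:
three diagnostic groups (AD, MCI, NC) plus MCI converter/nonconverter
subgroups, voxel time series built from shared band-limited network signals
whose coupling is reduced in affected groups, optional global / white-matter
/ CSF confound signals, Gaussian observation noise, and random-walk head
motion traces.

Generative model for a voxel v belonging to network k of subject i::

    y_v(t) = a_k * s_k(t) + sum_j c_j * g_j(t) + eps_v(t)

where ``s_k`` and the confounds ``g_j`` are unit-variance latent signals
band-limited to the analysis band (0.01-0.08 Hz by default) and ``eps`` is
iid Gaussian with standard deviation ``noise_sd``.  With zero confound
amplitudes the expected Pearson correlation between two voxels of the same
network is ``a_k**2 / (a_k**2 + noise_sd**2)``; off-network gray-matter
voxels carry confounds and noise only.

All randomness flows from the single ``CohortSpec.seed`` through a fixed
splitting rule (see :func:`generate_cohort`).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "Bold4D",
    "MotionTrace",
    "SubjectRecord",
    "NetworkROI",
    "CohortSpec",
    "CohortData",
    "generate_bold",
    "generate_cohort",
    "default_cohort_spec",
    "CLINICAL_GROUP_SUMMARIES",
    "MCI_SUBGROUP_BASELINE_SUMMARIES",
    "SCORE_RANGES",
]

GROUPS = ("AD", "MCI", "NC")
SCORE_NAMES = ("MMSE", "MoCA", "CDT", "AVLT_I", "AVLT_D", "AVLT_R")

#: Published per-group summary statistics (mean, SD, n) of the clinical
#: cohort this generator is parameterized to: demographics and
#: neuropsychological scores for 25 AD, 31 MCI and 42 control subjects.
#: Group F statistics for these rows are recomputable with
#: :func:`fcstrength.inference.anova_f_from_summary`.
CLINICAL_GROUP_SUMMARIES: dict[str, dict[str, tuple[float, float, int]]] = {
    "age": {"AD": (69.4, 11.1, 25), "MCI": (67.9, 9.5, 31), "NC": (65.6, 7.1, 42)},
    "education": {"AD": (8.3, 5.4, 25), "MCI": (10.1, 5.0, 31), "NC": (11.1, 4.9, 42)},
    "MMSE": {"AD": (16.8, 4.7, 25), "MCI": (23.5, 2.9, 31), "NC": (28.0, 2.3, 42)},
    "MoCA": {"AD": (12.8, 4.8, 24), "MCI": (18.3, 3.9, 22), "NC": (26.0, 2.8, 30)},
    "CDT": {"AD": (1.7, 1.1, 23), "MCI": (1.8, 0.8, 29), "NC": (2.9, 0.4, 38)},
    "AVLT_I": {"AD": (3.6, 1.5, 25), "MCI": (4.6, 1.3, 31), "NC": (9.3, 2.1, 42)},
    "AVLT_D": {"AD": (0.6, 1.1, 25), "MCI": (2.7, 2.2, 31), "NC": (10.4, 3.0, 42)},
    "AVLT_R": {"AD": (3.4, 3.1, 25), "MCI": (7.1, 3.9, 31), "NC": (12.4, 2.1, 42)},
}

#: Baseline summaries for the MCI converter (n=21) / nonconverter (n=10)
#: subgroups; pooled two-sample t statistics are recomputable with
#: :func:`fcstrength.inference.pooled_t_from_summary`.
MCI_SUBGROUP_BASELINE_SUMMARIES: dict[str, dict[str, tuple[float, float, int]]] = {
    "age": {"converter": (68.6, 9.3, 21), "nonconverter": (66.5, 10.4, 10)},
    "education": {"converter": (10.5, 4.6, 21), "nonconverter": (9.2, 5.9, 10)},
    "MMSE": {"converter": (23.5, 2.9, 21), "nonconverter": (23.6, 3.2, 10)},
    "MoCA": {"converter": (18.1, 3.7, 15), "nonconverter": (18.7, 4.5, 7)},
    "CDT": {"converter": (1.7, 0.9, 19), "nonconverter": (2.0, 0.7, 10)},
    "AVLT_I": {"converter": (4.4, 1.2, 21), "nonconverter": (4.9, 1.4, 10)},
    "AVLT_D": {"converter": (2.3, 1.9, 21), "nonconverter": (3.6, 2.6, 10)},
    "AVLT_R": {"converter": (6.6, 4.2, 21), "nonconverter": (8.1, 3.1, 10)},
}

#: Instrument ranges used to clip sampled scores.
SCORE_RANGES: dict[str, tuple[float, float]] = {
    "MMSE": (0.0, 30.0),
    "MoCA": (0.0, 30.0),
    "CDT": (0.0, 3.0),
    "AVLT_I": (0.0, 15.0),
    "AVLT_D": (0.0, 15.0),
    "AVLT_R": (-5.0, 15.0),
}

#: Male fraction per group (from the published 9/16, 14/17, 15/27 splits).
MALE_FRACTION = {"AD": 9 / 25, "MCI": 14 / 31, "NC": 15 / 42}


@dataclass
class Bold4D:
    """A 4D BOLD array (x, y, z, t) with voxel geometry and repetition time."""

    data: np.ndarray
    voxel_size_mm: tuple[float, float, float] = (3.0, 3.0, 3.0)
    tr_s: float = 2.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError(f"BOLD data must be 4D, got shape {self.data.shape}")
        if self.data.shape[3] < 2:
            raise ValueError("BOLD series needs at least 2 time points")
        if min(self.data.shape) < 1:
            raise ValueError("all BOLD dimensions must be >= 1")
        if any(v <= 0 for v in self.voxel_size_mm) or self.tr_s <= 0:
            raise ValueError("voxel size and TR must be strictly positive")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[3]

    @property
    def grid_dims(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_size_mm))


@dataclass
class MotionTrace:
    """Six rigid-body motion parameters per frame (translations mm, rotations rad)."""

    translations_mm: np.ndarray
    rotations_rad: np.ndarray

    def __post_init__(self) -> None:
        self.translations_mm = np.asarray(self.translations_mm, dtype=float)
        self.rotations_rad = np.asarray(self.rotations_rad, dtype=float)
        if self.translations_mm.shape != self.rotations_rad.shape:
            raise ValueError("translations and rotations must have identical shape")
        if self.translations_mm.ndim != 2 or self.translations_mm.shape[1] != 3:
            raise ValueError("motion traces must be t x 3 arrays")
        if not (np.isfinite(self.translations_mm).all() and np.isfinite(self.rotations_rad).all()):
            raise ValueError("motion parameters must be finite")

    @property
    def n_frames(self) -> int:
        return self.translations_mm.shape[0]

    def as_matrix(self) -> np.ndarray:
        """t x 6 matrix in the conventional order (3 translations, 3 rotations)."""
        return np.hstack([self.translations_mm, self.rotations_rad])


@dataclass
class SubjectRecord:
    id: str
    group: str
    mci_subgroup: str  # converter | nonconverter | not_applicable
    age_years: float
    sex: str  # M | F
    education_years: float
    scores: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}")
        if (self.mci_subgroup != "not_applicable") != (self.group == "MCI"):
            raise ValueError("mci_subgroup applies exactly to MCI subjects")
        if self.sex not in ("M", "F"):
            raise ValueError(f"sex must be M or F, got {self.sex!r}")

    @property
    def is_converter(self) -> bool:
        return self.mci_subgroup == "converter"


@dataclass(frozen=True)
class NetworkROI:
    """A named, fixed set of grid voxels sharing one latent network signal."""

    name: str
    voxels: tuple[tuple[int, int, int], ...]

    def index_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        idx = np.asarray(self.voxels)
        return idx[:, 0], idx[:, 1], idx[:, 2]

    def mask(self, grid_dims: Sequence[int]) -> np.ndarray:
        m = np.zeros(tuple(grid_dims), dtype=bool)
        m[self.index_arrays()] = True
        return m


# Default coupling weights.  The graded ordering NC > MCI-nonconverter >
# MCI-converter > AD encodes the reported direction of FCS loss in
# default-mode and occipital territory; the gap sizes are free parameters
# of the generator (no quantitative effect sizes are published).
DEFAULT_COUPLING = {
    "NC": 1.0,
    "MCI_nonconverter": 0.8,
    "MCI_converter": 0.55,
    "AD": 0.45,
}


def _coupling_key(record_group: str, subgroup: str) -> str:
    if record_group == "MCI":
        return f"MCI_{subgroup}"
    return record_group


@dataclass
class CohortSpec:
    """Full description of a synthetic cohort; the single source of randomness."""

    grid_dims: tuple[int, int, int] = (24, 24, 18)
    voxel_size_mm: tuple[float, float, float] = (3.0, 3.0, 3.0)
    n_per_group: dict[str, int] = field(
        default_factory=lambda: {"AD": 25, "MCI": 31, "NC": 42}
    )
    n_converters: int = 21
    network_rois: tuple[NetworkROI, ...] | None = None
    coupling_by_group: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COUPLING)
    )
    noise_sd: float = 1.0
    confound_amplitudes: dict[str, float] = field(
        default_factory=lambda: {"global": 0.5, "wm": 0.3, "csf": 0.3}
    )
    motion_sd: float = 0.05
    n_timepoints: int = 150
    tr_s: float = 2.0
    band_hz: tuple[float, float] = (0.01, 0.08)
    #: optional confounding knob: adds this multiple of (age z-score) to
    #: every subject's coupling deficit, coupling age to the planted effect.
    age_coupling_slope: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.network_rois is None:
            self.network_rois = default_network_rois(self.grid_dims)
        self.validate()

    def validate(self) -> None:
        if self.n_timepoints < 2:
            raise ValueError("n_timepoints must be >= 2")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.motion_sd < 0:
            raise ValueError("motion_sd must be nonnegative")
        if self.tr_s <= 0:
            raise ValueError("tr_s must be positive")
        counts = {g: int(self.n_per_group.get(g, 0)) for g in GROUPS}
        if any(c <= 0 for c in counts.values()):
            raise ValueError("every group needs at least one subject")
        if not 0 <= self.n_converters <= counts["MCI"]:
            raise ValueError("n_converters must lie in [0, n_per_group['MCI']]")
        seen: set[tuple[int, int, int]] = set()
        for roi in self.network_rois:
            for v in roi.voxels:
                if v in seen:
                    raise ValueError(f"network ROIs overlap at voxel {v}")
                if any(not 0 <= v[d] < self.grid_dims[d] for d in range(3)):
                    raise ValueError(f"ROI voxel {v} outside grid {self.grid_dims}")
                seen.add(v)
        for key, a in self.coupling_by_group.items():
            if not np.isfinite(a) or a < 0:
                raise ValueError(f"coupling weight for {key!r} must be finite and >= 0")

    def subject_coupling(self, record_group: str, subgroup: str) -> dict[str, float]:
        """Per-network coupling for one subject (identical across networks by default)."""
        a = self.coupling_by_group[_coupling_key(record_group, subgroup)]
        return {roi.name: a for roi in self.network_rois}

    def replace(self, **kwargs) -> "CohortSpec":
        return dataclasses.replace(self, **kwargs)


def default_network_rois(grid_dims: Sequence[int]) -> tuple[NetworkROI, ...]:
    """Two disjoint cuboid networks placed inside the brain ellipsoid.

    ``angular_like`` sits posterior-superior (default-mode territory),
    ``occipital_like`` posterior-inferior (visual territory).  Blocks scale
    with the grid so small test grids remain valid.
    """
    nx, ny, nz = grid_dims
    bx = max(2, nx // 4)
    by = max(2, ny // 4)
    bz = max(2, nz // 4)

    def block(x0: int, y0: int, z0: int) -> tuple[tuple[int, int, int], ...]:
        return tuple(
            (x, y, z)
            for x in range(x0, min(x0 + bx, nx))
            for y in range(y0, min(y0 + by, ny))
            for z in range(z0, min(z0 + bz, nz))
        )

    angular = block(nx // 2 - bx // 2, int(ny * 0.62), int(nz * 0.55))
    occipital = block(nx // 2 - bx // 2, int(ny * 0.72), max(0, int(nz * 0.2)))
    if set(angular) & set(occipital):  # tiny grids: shift occipital forward
        occipital = block(max(0, nx // 2 - bx - bx // 2 - 1), int(ny * 0.72), 0)
    return (
        NetworkROI("angular_like", angular),
        NetworkROI("occipital_like", occipital),
    )


def anatomy_masks(spec: CohortSpec) -> dict[str, np.ndarray]:
    """Brain / GM / WM / CSF compartments on the spec grid.

    The brain is an ellipsoid filling ~90% of each half-axis; a central core
    plays white matter and a small block next to it CSF; gray matter is the
    remainder of the ellipsoid.  Network ROI voxels are forced into GM.
    """
    nx, ny, nz = spec.grid_dims
    x, y, z = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij")
    cx, cy, cz = (nx - 1) / 2, (ny - 1) / 2, (nz - 1) / 2
    rx, ry, rz = nx * 0.45, ny * 0.45, nz * 0.45
    brain = ((x - cx) / rx) ** 2 + ((y - cy) / ry) ** 2 + ((z - cz) / rz) ** 2 <= 1.0

    wx = max(1, nx // 8)
    wm = np.zeros_like(brain)
    wm[
        int(cx - wx) : int(cx + wx) + 1,
        int(cy - wx) : int(cy + wx) + 1,
        int(cz - wx) : int(cz + wx) + 1,
    ] = True
    wm &= brain
    csf = np.zeros_like(brain)
    csf[
        int(cx - wx) : int(cx + wx) + 1,
        max(0, int(cy - 3 * wx)) : int(cy - wx),
        int(cz - wx) : int(cz + wx) + 1,
    ] = True
    csf &= brain & ~wm
    gm = brain & ~wm & ~csf
    for roi in spec.network_rois:
        m = roi.mask(spec.grid_dims)
        brain |= m
        gm |= m
        wm &= ~m
        csf &= ~m
    return {"brain": brain, "gm": gm, "wm": wm, "csf": csf}


def _band_limited_signal(rng: np.random.Generator, t: int, tr_s: float,
                         band: tuple[float, float]) -> np.ndarray:
    """Unit-variance white noise band-passed to ``band`` (Hz) via FFT masking."""
    x = rng.standard_normal(t)
    freqs = np.fft.rfftfreq(t, d=tr_s)
    spec = np.fft.rfft(x)
    keep = (freqs >= band[0]) & (freqs <= band[1])
    if not keep.any():  # degenerate short series: keep everything but DC
        keep = freqs > 0
    spec[~keep] = 0.0
    y = np.fft.irfft(spec, n=t)
    sd = y.std()
    if sd == 0:
        raise ValueError("degenerate latent signal (zero variance)")
    return y / sd


def generate_bold(
    spec: CohortSpec,
    subject_coupling: Mapping[str, float],
    seed: int | np.random.SeedSequence,
) -> tuple[Bold4D, MotionTrace]:
    """Generate one subject's BOLD volume and motion trace.

    ``subject_coupling`` maps network name -> coupling weight ``a``.  The
    call is deterministic for a fixed seed: latent network signals are drawn
    first (in ``spec.network_rois`` order), then the three confound signals
    (global, wm, csf), then observation noise, then motion.
    """
    spec.validate()
    rng = np.random.default_rng(seed)
    t = spec.n_timepoints
    masks = anatomy_masks(spec)

    latents = {
        roi.name: _band_limited_signal(rng, t, spec.tr_s, spec.band_hz)
        for roi in spec.network_rois
    }
    g_global = _band_limited_signal(rng, t, spec.tr_s, spec.band_hz)
    g_wm = _band_limited_signal(rng, t, spec.tr_s, spec.band_hz)
    g_csf = _band_limited_signal(rng, t, spec.tr_s, spec.band_hz)

    data = np.zeros(spec.grid_dims + (t,), dtype=np.float64)
    amp = spec.confound_amplitudes
    brain = masks["brain"]
    data[brain] += amp.get("global", 0.0) * g_global
    # compartments carry their own physiological signals at unit amplitude
    # so confound extraction has something to find; they also leak into GM
    # at the configured amplitudes.
    data[masks["wm"]] += g_wm
    data[masks["csf"]] += g_csf
    data[masks["gm"]] += amp.get("wm", 0.0) * g_wm + amp.get("csf", 0.0) * g_csf

    for roi in spec.network_rois:
        a = float(subject_coupling.get(roi.name, 0.0))
        if a != 0.0:
            ix, iy, iz = roi.index_arrays()
            data[ix, iy, iz, :] += a * latents[roi.name]

    if spec.noise_sd > 0:
        data[brain] += rng.normal(0.0, spec.noise_sd, size=(int(brain.sum()), t))

    steps_t = rng.normal(0.0, spec.motion_sd, size=(t, 3))
    steps_r = rng.normal(0.0, spec.motion_sd / 50.0, size=(t, 3))
    motion = MotionTrace(np.cumsum(steps_t, axis=0), np.cumsum(steps_r, axis=0))
    bold = Bold4D(data, voxel_size_mm=spec.voxel_size_mm, tr_s=spec.tr_s)
    return bold, motion


@dataclass
class CohortData:
    """A generated cohort: parallel lists plus per-subject GM probability maps."""

    spec: CohortSpec
    subjects: list[SubjectRecord]
    bolds: list[Bold4D]
    motions: list[MotionTrace]
    gm_probability_maps: list[np.ndarray]

    def __iter__(self):
        return iter(zip(self.subjects, self.bolds, self.motions))

    def __len__(self) -> int:
        return len(self.subjects)

    def subject_table(self):
        import pandas as pd

        rows = []
        for s in self.subjects:
            row = {
                "id": s.id,
                "group": s.group,
                "mci_subgroup": s.mci_subgroup,
                "age": s.age_years,
                "sex": s.sex,
                "education": s.education_years,
            }
            row.update({k: s.scores.get(k, np.nan) for k in SCORE_NAMES})
            rows.append(row)
        return pd.DataFrame(rows)


def _sample_scores(rng: np.random.Generator, group: str, subgroup: str) -> dict[str, float]:
    scores: dict[str, float] = {}
    for name in SCORE_NAMES:
        if group == "MCI" and subgroup in ("converter", "nonconverter"):
            mean, sd, _ = MCI_SUBGROUP_BASELINE_SUMMARIES[name][subgroup]
        else:
            mean, sd, _ = CLINICAL_GROUP_SUMMARIES[name][group]
        lo, hi = SCORE_RANGES[name]
        scores[name] = float(np.clip(rng.normal(mean, sd), lo, hi))
    return scores


def generate_cohort(spec: CohortSpec) -> CohortData:
    """Generate the full cohort deterministically from ``spec.seed``.

    Seed-splitting rule: ``SeedSequence(spec.seed)`` is spawned into
    ``1 + N`` children — child 0 drives the subject table (demographics,
    scores, converter assignment order, GM map noise), child ``1 + i``
    drives subject ``i``'s BOLD, motion and GM map, with subjects ordered
    AD block, MCI block (converters first), NC block.
    """
    spec.validate()
    counts = {g: int(spec.n_per_group[g]) for g in GROUPS}
    n_total = sum(counts.values())
    ss = np.random.SeedSequence(spec.seed)
    children = ss.spawn(1 + n_total)
    table_rng = np.random.default_rng(children[0])
    masks = anatomy_masks(spec)

    base_prob = np.full(spec.grid_dims, 0.01)
    base_prob[masks["gm"]] = 0.8
    base_prob[masks["wm"]] = 0.15
    base_prob[masks["csf"]] = 0.05
    for roi in spec.network_rois:
        base_prob[roi.mask(spec.grid_dims)] = 0.9

    subjects: list[SubjectRecord] = []
    bolds: list[Bold4D] = []
    motions: list[MotionTrace] = []
    gm_maps: list[np.ndarray] = []

    plan: list[tuple[str, str]] = []
    plan += [("AD", "not_applicable")] * counts["AD"]
    plan += [("MCI", "converter")] * spec.n_converters
    plan += [("MCI", "nonconverter")] * (counts["MCI"] - spec.n_converters)
    plan += [("NC", "not_applicable")] * counts["NC"]

    for i, (group, subgroup) in enumerate(plan):
        age_row = (
            MCI_SUBGROUP_BASELINE_SUMMARIES["age"][subgroup]
            if group == "MCI"
            else CLINICAL_GROUP_SUMMARIES["age"][group]
        )
        edu_row = (
            MCI_SUBGROUP_BASELINE_SUMMARIES["education"][subgroup]
            if group == "MCI"
            else CLINICAL_GROUP_SUMMARIES["education"][group]
        )
        age = float(np.clip(table_rng.normal(age_row[0], age_row[1]), 45.0, 95.0))
        education = float(np.clip(table_rng.normal(edu_row[0], edu_row[1]), 0.0, 22.0))
        sex = "M" if table_rng.random() < MALE_FRACTION[group] else "F"
        record = SubjectRecord(
            id=f"sub-{i:03d}",
            group=group,
            mci_subgroup=subgroup,
            age_years=age,
            sex=sex,
            education_years=education,
            scores=_sample_scores(table_rng, group, subgroup),
        )
        coupling = spec.subject_coupling(group, subgroup)
        if spec.age_coupling_slope != 0.0:
            zage = (age - 67.0) / 9.0
            coupling = {
                k: max(0.0, a - spec.age_coupling_slope * zage) for k, a in coupling.items()
            }
        subj_ss = children[1 + i]
        bold_seed, gm_seed = subj_ss.spawn(2)
        bold, motion = generate_bold(spec, coupling, bold_seed)
        gm_rng = np.random.default_rng(gm_seed)
        gm_map = np.clip(base_prob + gm_rng.normal(0.0, 0.03, spec.grid_dims), 0.0, 1.0)
        # keep ROI voxels comfortably above any sensible GM cutoff
        for roi in spec.network_rois:
            m = roi.mask(spec.grid_dims)
            gm_map[m] = np.maximum(gm_map[m], 0.6)
        subjects.append(record)
        bolds.append(bold)
        motions.append(motion)
        gm_maps.append(gm_map)

    return CohortData(spec, subjects, bolds, motions, gm_maps)


def default_cohort_spec(**overrides) -> CohortSpec:
    """The default study conditions; keyword overrides for scaled-down runs."""
    return CohortSpec(**overrides)
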