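"""Robustness suite for the converter-vs-nonconverter FCS comparison.

Re-runs the ROI-level MCI-converter vs MCI-nonconverter comparison under
three methodological axes: the FCS correlation threshold (0.1 / 0.2 / 0.3),
mean framewise displacement added as a nuisance covariate, and global
signal regression switched off.  The ROI statistic is the subject-mean FCS
inside each region of interest, compared between subgroups with age and
sex as covariates.  One correlation pass per subject per preprocessing
variant feeds all threshold variants.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .cohort import CohortData
from .connectivity import fcs_from_correlations, pairwise_correlations
from .inference import posthoc_t_map
from .preprocess import clean_subject, framewise_displacement, group_gm_mask

__all__ = ["ValidationVariant", "ValidationReport", "run_validation_suite"]

DEFAULT_VARIANTS = ("r0.1", "r0.2", "r0.3", "fd_covariate", "no_gsr")


@dataclass(frozen=True)
class ValidationVariant:
    variant_id: str
    r_threshold: float
    fd_covariate: bool
    gsr: bool


def _parse_variant(variant_id: str) -> ValidationVariant:
    if variant_id.startswith("r0."):
        return ValidationVariant(variant_id, float(variant_id[1:]), False, True)
    if variant_id == "fd_covariate":
        return ValidationVariant(variant_id, 0.2, True, True)
    if variant_id == "no_gsr":
        return ValidationVariant(variant_id, 0.2, False, False)
    raise ValueError(f"unknown variant id {variant_id!r}")


@dataclass
class ValidationReport:
    records: list[dict] = field(default_factory=list)
    group_fd_p: float = float("nan")

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.records)


def _roi_t(
    roi_values: np.ndarray,
    converter: np.ndarray,
    covariates: np.ndarray,
) -> tuple[float, float]:
    """Covariate-adjusted converter-minus-nonconverter t on one scalar per subject."""
    maps_a = [np.array([[[v]]]) for v in roi_values[converter]]
    maps_b = [np.array([[[v]]]) for v in roi_values[~converter]]
    cov = np.vstack([covariates[converter], covariates[~converter]])
    stat = posthoc_t_map(maps_a, maps_b, covariates=cov,
                         restrict_mask=np.ones((1, 1, 1), bool))
    t = float(stat.values[0, 0, 0])
    p = 2.0 * stats.t.sf(abs(t), stat.df)
    return t, p


def run_validation_suite(
    cohort: CohortData,
    roi_masks: dict[str, np.ndarray] | None = None,
    variants: tuple[str, ...] = DEFAULT_VARIANTS,
    gm_cutoff: float = 0.2,
    band_hz: tuple[float, float] = (0.01, 0.08),
    fcs_mode: str = "zsum",
) -> ValidationReport:
    """Run every requested variant on the cohort's MCI subjects.

    ``roi_masks`` defaults to the cohort's planted network ROIs.  Each
    record holds the variant settings and, per ROI, the adjusted
    converter-vs-nonconverter t and two-tailed p.  The report also carries
    the p of the subgroup difference in mean FD (pooled two-sample t).
    """
    from .cohort import anatomy_masks

    spec = cohort.spec
    if roi_masks is None:
        roi_masks = {roi.name: roi.mask(spec.grid_dims) for roi in spec.network_rois}
    for name, m in roi_masks.items():
        if not np.asarray(m).any():
            raise ValueError(f"ROI mask {name!r} is empty")
    variant_defs = [_parse_variant(v) for v in variants]

    mci = [i for i, s in enumerate(cohort.subjects) if s.group == "MCI"]
    if not mci:
        raise ValueError("cohort has no MCI subjects")
    converter = np.array([cohort.subjects[i].is_converter for i in mci])
    age = np.array([cohort.subjects[i].age_years for i in mci])
    sex = np.array([1.0 if cohort.subjects[i].sex == "M" else 0.0 for i in mci])
    base_cov = np.column_stack([age, sex])

    gm = group_gm_mask([cohort.gm_probability_maps[i] for i in mci], cutoff=gm_cutoff)
    compartments = anatomy_masks(spec)
    conf_masks = {"global": gm.include, "wm": compartments["wm"], "csf": compartments["csf"]}

    mean_fd = np.array(
        [framewise_displacement(cohort.motions[i]).mean_fd_mm for i in mci]
    )
    fd_t, fd_df = _pooled_t(mean_fd[converter], mean_fd[~converter])
    group_fd_p = 2.0 * stats.t.sf(abs(fd_t), fd_df)

    # one preprocessing + correlation pass per GSR setting; every threshold
    # variant reuses the corresponding correlation matrices
    needed_gsr = sorted({v.gsr for v in variant_defs}, reverse=True)
    corr_cache: dict[bool, list[tuple[np.ndarray, np.ndarray]]] = {}
    for gsr in needed_gsr:
        passes = []
        for i in mci:
            cleaned = clean_subject(
                cohort.bolds[i], cohort.motions[i], conf_masks,
                low_hz=band_hz[0], high_hz=band_hz[1], gsr=gsr,
            )
            passes.append(pairwise_correlations(cleaned, gm))
        corr_cache[gsr] = passes

    records = []
    for v in variant_defs:
        roi_fcs: dict[str, np.ndarray] = {name: np.empty(len(mci)) for name in roi_masks}
        for si, (r, idx) in enumerate(corr_cache[v.gsr]):
            fcs = fcs_from_correlations(
                r, idx, spec.grid_dims, gm.include,
                r_threshold=v.r_threshold, mode=fcs_mode,
            )
            for name, m in roi_masks.items():
                roi_fcs[name][si] = fcs.values[np.asarray(m, bool)].mean()
        cov = np.column_stack([base_cov, mean_fd]) if v.fd_covariate else base_cov
        rec = {
            "variant_id": v.variant_id,
            "r_threshold": v.r_threshold,
            "fd_covariate": v.fd_covariate,
            "gsr": v.gsr,
            "group_fd_p": group_fd_p,
        }
        for name in roi_masks:
            t, p = _roi_t(roi_fcs[name], converter, cov)
            rec[f"{name}_t"] = t
            rec[f"{name}_p"] = p
        records.append(rec)
    return ValidationReport(records=records, group_fd_p=group_fd_p)


def _pooled_t(a: np.ndarray, b: np.ndarray) -> tuple[float, int]:
    res = stats.ttest_ind(a, b, equal_var=True)
    return float(res.statistic), len(a) + len(b) - 2
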