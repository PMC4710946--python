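"""Covariate-adjusted voxelwise group statistics and summary-statistic tests.

Voxelwise inference follows the general-linear-model route: the group
effect on FCS is the partial F from nested least-squares fits (full model:
intercept + group dummies + covariates; reduced model: intercept +
covariates), post-hoc two-group contrasts are t statistics for the group
coefficient, and behavior associations are t statistics for a continuous
score slope — all adjusted for age and sex by default.

Closed-form tests from published summary statistics (mean, SD, n) are also
provided: the one-way ANOVA F across groups and the pooled-variance
two-sample t, which recover the printed group comparisons of the cohort's
demographic and neuropsychological tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .connectivity import FcsMap

__all__ = [
    "StatMap",
    "GroupSummary",
    "stack_maps",
    "ancova_f_map",
    "posthoc_t_map",
    "behavior_association_map",
    "anova_f_from_summary",
    "pooled_t_from_summary",
]

#: |t| is capped here when the residual variance underflows (perfect fits).
T_CAP = 1e12


@dataclass
class StatMap:
    """A voxelwise F or t map with its degrees of freedom."""

    values: np.ndarray
    stat_kind: str  # "F" | "t"
    df: tuple[int, int] | int
    mask: np.ndarray
    design_description: str = ""
    slopes: np.ndarray | None = None  # for behavior maps: the fitted slope

    def p_values(self) -> np.ndarray:
        """Voxelwise p map: upper-tail for F, two-tailed for t."""
        p = np.ones_like(self.values)
        v = self.values[self.mask]
        if self.stat_kind == "F":
            df1, df2 = self.df
            p[self.mask] = stats.f.sf(v, df1, df2)
        else:
            p[self.mask] = 2.0 * stats.t.sf(np.abs(v), self.df)
        return p

    def threshold_value(self, p: float) -> float:
        """Stat value cutting the voxelwise p level (two-tailed for t)."""
        if self.stat_kind == "F":
            df1, df2 = self.df
            return float(stats.f.isf(p, df1, df2))
        return float(stats.t.isf(p / 2.0, self.df))


@dataclass
class GroupSummary:
    """Published per-group summary: label, mean, SD, n."""

    label: str
    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be nonnegative")
        if self.n < 2:
            raise ValueError("each group needs n >= 2")


def stack_maps(maps: Sequence[FcsMap | np.ndarray], mask: np.ndarray) -> np.ndarray:
    """Subjects x voxels data matrix over ``mask`` (fixed C-order voxel order)."""
    mask = np.asarray(mask, dtype=bool)
    rows = []
    for m in maps:
        arr = m.values if isinstance(m, FcsMap) else np.asarray(m)
        rows.append(arr[mask])
    return np.asarray(rows)


def _as_design(n: int, covariates: np.ndarray | None) -> np.ndarray:
    if covariates is None:
        return np.empty((n, 0))
    cov = np.asarray(covariates, dtype=float)
    if cov.ndim == 1:
        cov = cov[:, None]
    if cov.shape[0] != n:
        raise ValueError(f"covariates have {cov.shape[0]} rows, expected {n}")
    return cov


def _check_full_rank(design: np.ndarray, what: str) -> None:
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError(f"rank-deficient {what} design matrix")


def _rss(design: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Residual sum of squares per column of y under least squares on design."""
    q, _ = np.linalg.qr(design)
    resid = y - q @ (q.T @ y)
    return (resid**2).sum(axis=0)


def ancova_f_map(
    maps: Sequence[FcsMap | np.ndarray],
    groups: Sequence[str],
    covariates: np.ndarray | None = None,
    mask: np.ndarray | None = None,
) -> StatMap:
    """Partial F for the group factor at every mask voxel.

    df1 = G - 1, df2 = N - G - k with k covariate columns.  With zero
    covariates this reduces exactly to the one-way ANOVA F.
    """
    groups = list(groups)
    n = len(groups)
    if len(maps) != n:
        raise ValueError("one map per subject required")
    levels = sorted(set(groups))
    if len(levels) < 2:
        raise ValueError("need at least two groups")
    if mask is None:
        first = maps[0]
        mask = first.mask if isinstance(first, FcsMap) else np.ones(first.shape, bool)
    y = stack_maps(maps, mask)
    cov = _as_design(n, covariates)
    k = cov.shape[1]
    dummies = np.column_stack([[1.0 if g == lv else 0.0 for g in groups] for lv in levels[1:]])
    intercept = np.ones((n, 1))
    full = np.hstack([intercept, dummies, cov])
    reduced = np.hstack([intercept, cov])
    _check_full_rank(full, "ANCOVA full")
    g = len(levels)
    df1 = g - 1
    df2 = n - g - k
    if df2 <= 0:
        raise ValueError("nonpositive error degrees of freedom")
    rss_full = _rss(full, y)
    rss_red = _rss(reduced, y)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = ((rss_red - rss_full) / df1) / (rss_full / df2)
    f = np.where(np.isfinite(f), f, 0.0)
    f = np.maximum(f, 0.0)
    values = np.zeros(np.asarray(mask).shape)
    values[mask] = f
    return StatMap(values, "F", (df1, df2), np.asarray(mask, bool),
                   design_description=f"group ({'/'.join(levels)}) + {k} covariate(s)")


def _coefficient_t(
    y: np.ndarray, design: np.ndarray, coef_index: int, what: str
) -> tuple[np.ndarray, np.ndarray, int]:
    """t statistic and estimate for one coefficient, per column of y."""
    _check_full_rank(design, what)
    n, p = design.shape
    df = n - p
    if df <= 0:
        raise ValueError("nonpositive error degrees of freedom")
    xtx_inv = np.linalg.inv(design.T @ design)
    beta = xtx_inv @ design.T @ y
    resid = y - design @ beta
    sigma2 = (resid**2).sum(axis=0) / df
    se = np.sqrt(np.maximum(sigma2 * xtx_inv[coef_index, coef_index], 0.0))
    b = beta[coef_index]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = b / se
    t = np.where(se > 0, t, np.sign(b) * T_CAP)
    t = np.clip(t, -T_CAP, T_CAP)
    return t, b, df


def posthoc_t_map(
    maps_a: Sequence[FcsMap | np.ndarray],
    maps_b: Sequence[FcsMap | np.ndarray],
    covariates: np.ndarray | None = None,
    restrict_mask: np.ndarray | None = None,
) -> StatMap:
    """Covariate-adjusted two-group t map; sign convention is (a - b).

    Covariate rows are ordered as ``list(maps_a) + list(maps_b)``.  Without
    covariates the statistic equals the pooled two-sample t.
    """
    na, nb = len(maps_a), len(maps_b)
    if na < 2 or nb < 2:
        raise ValueError("each group needs at least 2 subjects")
    if restrict_mask is None:
        first = maps_a[0]
        restrict_mask = first.mask if isinstance(first, FcsMap) else np.ones(first.shape, bool)
    restrict_mask = np.asarray(restrict_mask, dtype=bool)
    y = stack_maps(list(maps_a) + list(maps_b), restrict_mask)
    n = na + nb
    cov = _as_design(n, covariates)
    indicator = np.concatenate([np.ones(na), np.zeros(nb)])
    design = np.column_stack([np.ones(n), indicator, *cov.T])
    t, _, df = _coefficient_t(y, design, 1, "post-hoc t")
    values = np.zeros(restrict_mask.shape)
    values[restrict_mask] = t
    return StatMap(values, "t", df, restrict_mask,
                   design_description=f"group a-b + {cov.shape[1]} covariate(s)")


def behavior_association_map(
    maps: Sequence[FcsMap | np.ndarray],
    score: np.ndarray,
    covariates: np.ndarray | None = None,
    mask: np.ndarray | None = None,
) -> StatMap:
    """t map for the slope of FCS on a clinical score, adjusted for covariates."""
    score = np.asarray(score, dtype=float)
    n = len(maps)
    if score.shape != (n,):
        raise ValueError("score must be one value per subject")
    if np.ptp(score) == 0:
        raise ValueError("score has no variance")
    if mask is None:
        first = maps[0]
        mask = first.mask if isinstance(first, FcsMap) else np.ones(first.shape, bool)
    mask = np.asarray(mask, dtype=bool)
    y = stack_maps(maps, mask)
    cov = _as_design(n, covariates)
    design = np.column_stack([np.ones(n), score, *cov.T])
    t, slopes, df = _coefficient_t(y, design, 1, "behavior GLM")
    values = np.zeros(mask.shape)
    values[mask] = t
    slope_map = np.zeros(mask.shape)
    slope_map[mask] = slopes
    return StatMap(values, "t", df, mask, slopes=slope_map,
                   design_description=f"score slope + {cov.shape[1]} covariate(s)")


def anova_f_from_summary(groups: Sequence[GroupSummary]) -> tuple[float, int, int]:
    """One-way ANOVA F from per-group (mean, SD, n) summaries.

    F = [sum n_g (m_g - m̄)² / (G-1)] / [sum (n_g-1) s_g² / (N-G)] with m̄
    the n-weighted grand mean.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    ns = np.array([g.n for g in groups], dtype=float)
    ms = np.array([g.mean for g in groups])
    sds = np.array([g.sd for g in groups])
    n_total = ns.sum()
    grand = (ns * ms).sum() / n_total
    df1 = len(groups) - 1
    df2 = int(n_total) - len(groups)
    msb = (ns * (ms - grand) ** 2).sum() / df1
    msw = ((ns - 1) * sds**2).sum() / df2
    if msw == 0:
        if msb == 0:
            raise ValueError("all SDs zero with equal means: F undefined")
        return float("inf"), df1, df2
    return float(msb / msw), df1, df2


def pooled_t_from_summary(a: GroupSummary, b: GroupSummary) -> tuple[float, int]:
    """Pooled-variance two-sample t from summaries; df = n_a + n_b - 2."""
    df = a.n + b.n - 2
    sp2 = ((a.n - 1) * a.sd**2 + (b.n - 1) * b.sd**2) / df
    if sp2 == 0:
        if a.mean == b.mean:
            raise ValueError("zero pooled variance with equal means: t undefined")
        return float("inf") if a.mean > b.mean else float("-inf"), df
    t = (a.mean - b.mean) / np.sqrt(sp2 * (1.0 / a.n + 1.0 / b.n))
    return float(t), df
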