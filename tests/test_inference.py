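"""Group inference: GLM maps vs closed-form oracles, summary tests, calibration."""

import numpy as np
import pytest
from scipy import stats

from fcstrength.inference import (
    GroupSummary,
    T_CAP,
    ancova_f_map,
    anova_f_from_summary,
    behavior_association_map,
    pooled_t_from_summary,
    posthoc_t_map,
)


def _cube_maps(rng, n, shape=(4, 4, 2)):
    return [rng.standard_normal(shape) for _ in range(n)]


def _summary(label, x):
    return GroupSummary(label, float(np.mean(x)), float(np.std(x, ddof=1)), len(x))


class TestSummaryTests:
    def test_anova_matches_mmse_row(self):
        groups = [
            GroupSummary("AD", 16.8, 4.7, 25),
            GroupSummary("MCI", 23.5, 2.9, 31),
            GroupSummary("NC", 28.0, 2.3, 42),
        ]
        f, df1, df2 = anova_f_from_summary(groups)
        assert (df1, df2) == (2, 95)
        assert f == pytest.approx(93.04, rel=0.02)

    def test_anova_equal_means_give_zero(self):
        groups = [GroupSummary(g, 5.0, s, 10) for g, s in (("a", 1.0), ("b", 2.0))]
        f, _, _ = anova_f_from_summary(groups)
        assert f == 0.0

    def test_anova_degenerate_rejected(self):
        groups = [GroupSummary("a", 5.0, 0.0, 10), GroupSummary("b", 5.0, 0.0, 10)]
        with pytest.raises(ValueError, match="undefined"):
            anova_f_from_summary(groups)

    def test_anova_matches_raw_data_f(self):
        rng = np.random.default_rng(0)
        xs = [rng.standard_normal(n) + m for n, m in ((8, 0.0), (12, 1.0), (9, 0.4))]
        f_raw = stats.f_oneway(*xs).statistic
        f_sum, _, _ = anova_f_from_summary([_summary(str(i), x) for i, x in enumerate(xs)])
        assert f_sum == pytest.approx(f_raw, abs=1e-10)

    def test_pooled_t_matches_age_row(self):
        t, df = pooled_t_from_summary(
            GroupSummary("MCI-c", 68.6, 9.3, 21), GroupSummary("MCI-nc", 66.5, 10.4, 10)
        )
        assert df == 29
        assert t == pytest.approx(0.57, abs=0.02)

    def test_pooled_t_equal_means_zero(self):
        t, _ = pooled_t_from_summary(
            GroupSummary("a", 3.0, 1.0, 10), GroupSummary("b", 3.0, 2.0, 12)
        )
        assert t == 0.0

    def test_pooled_t_matches_raw_data_oracle(self):
        # raw vectors affine-standardized to hit the summaries exactly
        rng = np.random.default_rng(1)

        def exact(n, mean, sd):
            z = rng.standard_normal(n)
            z = (z - z.mean()) / z.std(ddof=1)
            return mean + sd * z

        a, b = exact(14, 2.3, 1.1), exact(9, 1.7, 0.8)
        t_raw = stats.ttest_ind(a, b, equal_var=True).statistic
        t_sum, _ = pooled_t_from_summary(_summary("a", a), _summary("b", b))
        assert t_sum == pytest.approx(t_raw, abs=1e-10)


class TestAncovaMap:
    def test_no_covariates_equals_per_voxel_summary_anova(self):
        rng = np.random.default_rng(2)
        groups = ["a"] * 8 + ["b"] * 10 + ["c"] * 7
        maps = _cube_maps(rng, len(groups))
        stat = ancova_f_map(maps, groups, covariates=None,
                            mask=np.ones((4, 4, 2), bool))
        data = np.array([m.reshape(-1) for m in maps])
        for v in range(data.shape[1]):
            per_group = [data[np.array(groups) == g, v] for g in ("a", "b", "c")]
            f_oracle, _, _ = anova_f_from_summary(
                [_summary(g, x) for g, x in zip("abc", per_group)]
            )
            assert stat.values.reshape(-1)[v] == pytest.approx(f_oracle, abs=1e-8)

    def test_f_equals_t_squared_for_two_groups(self):
        rng = np.random.default_rng(3)
        maps = _cube_maps(rng, 16)
        groups = ["a"] * 9 + ["b"] * 7
        f = ancova_f_map(maps, groups, mask=np.ones((4, 4, 2), bool))
        t = posthoc_t_map(maps[:9], maps[9:], restrict_mask=np.ones((4, 4, 2), bool))
        assert np.allclose(f.values, t.values**2, atol=1e-8)

    def test_collinear_covariate_rejected(self):
        rng = np.random.default_rng(4)
        groups = ["a"] * 5 + ["b"] * 5
        maps = _cube_maps(rng, 10)
        dummy = np.array([1.0] * 5 + [0.0] * 5)[:, None]  # == group indicator
        with pytest.raises(ValueError, match="rank-deficient"):
            ancova_f_map(maps, groups, covariates=dummy)

    def test_irrelevant_covariate_shifts_df2_by_one(self):
        rng = np.random.default_rng(5)
        groups = ["a"] * 10 + ["b"] * 10 + ["c"] * 10
        maps = [rng.standard_normal((3, 3, 2)) + (3.0 if g == "c" else 0.0)
                for g in groups]
        cov = rng.standard_normal((30, 1))
        f0 = ancova_f_map(maps, groups, mask=np.ones((3, 3, 2), bool))
        f1 = ancova_f_map(maps, groups, covariates=cov, mask=np.ones((3, 3, 2), bool))
        assert f0.df[1] - f1.df[1] == 1
        # the large planted group effect survives the extra covariate
        assert (f1.values > f1.threshold_value(0.01)).all()

    def test_type_one_error_calibrated_on_null(self):
        # iid null voxels, random labels: P<0.05 exceedance within 99% CI
        rng = np.random.default_rng(6)
        n, v = 60, 2000
        maps = [rng.standard_normal((v, 1, 1)) for _ in range(n)]
        groups = list(rng.permutation(["a"] * 20 + ["b"] * 20 + ["c"] * 20))
        stat = ancova_f_map(maps, groups, mask=np.ones((v, 1, 1), bool))
        rate = (stat.p_values()[stat.mask] < 0.05).mean()
        ci = 2.576 * np.sqrt(0.05 * 0.95 / v)
        assert abs(rate - 0.05) < ci


class TestPosthocMap:
    def test_identical_groups_give_zero_t(self):
        rng = np.random.default_rng(7)
        maps = _cube_maps(rng, 6)
        stat = posthoc_t_map(maps, [m.copy() for m in maps],
                             restrict_mask=np.ones((4, 4, 2), bool))
        assert np.allclose(stat.values, 0.0, atol=1e-8)

    def test_no_covariates_equals_pooled_t(self):
        rng = np.random.default_rng(8)
        a, b = _cube_maps(rng, 9), _cube_maps(rng, 6)
        stat = posthoc_t_map(a, b, restrict_mask=np.ones((4, 4, 2), bool))
        xa = np.array([m.reshape(-1) for m in a])
        xb = np.array([m.reshape(-1) for m in b])
        expected = stats.ttest_ind(xa, xb, axis=0, equal_var=True).statistic
        assert np.abs(stat.values.reshape(-1) - expected).max() < 1e-8

    def test_sign_convention_a_minus_b(self):
        shape = (2, 2, 1)
        a = [np.full(shape, 3.0) + 0.01 * i for i in range(4)]
        b = [np.full(shape, 1.0) + 0.01 * i for i in range(4)]
        stat = posthoc_t_map(a, b, restrict_mask=np.ones(shape, bool))
        assert (stat.values > 0).all()

    def test_restrict_mask_limits_computation(self):
        rng = np.random.default_rng(9)
        a, b = _cube_maps(rng, 5), _cube_maps(rng, 5)
        mask = np.zeros((4, 4, 2), bool)
        mask[0, 0, 0] = True
        stat = posthoc_t_map(a, b, restrict_mask=mask)
        assert np.allclose(stat.values[~mask], 0.0)


class TestBehaviorMap:
    def test_perfect_linear_relation_recovers_slope(self):
        score = np.linspace(10, 30, 12)
        maps = [np.full((2, 2, 1), 2.0 * s) for s in score]
        stat = behavior_association_map(maps, score, mask=np.ones((2, 2, 1), bool))
        assert np.allclose(stat.slopes[stat.mask], 2.0, atol=1e-8)
        assert (np.abs(stat.values[stat.mask]) == T_CAP).all()

    def test_slope_matches_least_squares_oracle(self):
        rng = np.random.default_rng(10)
        n = 25
        score = rng.standard_normal(n)
        cov = rng.standard_normal((n, 2))
        maps = [rng.standard_normal((3, 2, 1)) for _ in range(n)]
        stat = behavior_association_map(maps, score, cov, np.ones((3, 2, 1), bool))
        y = np.array([m.reshape(-1) for m in maps])
        x = np.column_stack([np.ones(n), score, cov])
        beta = np.linalg.lstsq(x, y, rcond=None)[0]
        assert np.abs(stat.slopes.reshape(-1) - beta[1]) .max() < 1e-8

    def test_null_slopes_center_at_zero(self):
        rng = np.random.default_rng(11)
        n, v = 40, 500
        score = rng.standard_normal(n)
        maps = [rng.standard_normal((v, 1, 1)) for _ in range(n)]
        stat = behavior_association_map(maps, score, mask=np.ones((v, 1, 1), bool))
        assert abs(stat.slopes[stat.mask].mean()) < 3.0 / np.sqrt(v * (n - 2))

    def test_constant_score_rejected(self):
        maps = [np.zeros((2, 2, 1))] * 5
        with pytest.raises(ValueError, match="variance"):
            behavior_association_map(maps, np.ones(5))
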