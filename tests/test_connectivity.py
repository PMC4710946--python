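"""FCS and seed-map correctness against brute-force correlation oracles."""

import numpy as np
import pytest

from fcstrength.cohort import Bold4D
from fcstrength.connectivity import (
    MAX_ABS_R,
    compute_fcs,
    fcs_from_correlations,
    fisher_z,
    pairwise_correlations,
    seed_fc_map,
    seed_timecourse,
)
from fcstrength.preprocess import GMMask


def _bold_from_series(series):
    """(V, T) series laid out along the first grid axis."""
    series = np.asarray(series, dtype=float)
    v, t = series.shape
    data = np.zeros((v, 1, 1, t))
    data[:, 0, 0, :] = series
    return Bold4D(data, (3.0, 3.0, 3.0), 2.0)


def _full_mask(bold):
    shape = bold.grid_dims
    return GMMask(np.ones(shape, bool), np.ones(shape))


def brute_force_fcs(series, r_threshold=0.2, mode="zsum"):
    """O(n^2) double-loop oracle using numpy.corrcoef per pair."""
    v = len(series)
    out = np.zeros(v)
    for i in range(v):
        for j in range(v):
            if i == j:
                continue
            r = np.corrcoef(series[i], series[j])[0, 1]
            if r > r_threshold:
                if mode == "zsum":
                    out[i] += np.arctanh(np.clip(r, -MAX_ABS_R, MAX_ABS_R))
                elif mode == "rsum":
                    out[i] += r
                else:
                    out[i] += 1
    return out


class TestFisherZ:
    @pytest.mark.parametrize(
        "r,expected",
        [(0.0, 0.0), (0.2, 0.202733), (-0.5, -0.549306)],
    )
    def test_reference_values(self, r, expected):
        assert fisher_z(r) == pytest.approx(expected, abs=1e-6)

    def test_odd_and_increasing(self):
        rs = np.linspace(-0.9, 0.9, 19)
        zs = fisher_z(rs)
        assert np.allclose(zs, -fisher_z(-rs))
        assert (np.diff(zs) > 0).all()

    def test_out_of_range_clipped_to_finite(self):
        z = fisher_z(1.0)
        assert np.isfinite(z)
        assert z == pytest.approx(np.arctanh(MAX_ABS_R))


class TestComputeFcs:
    def test_orthogonal_series_give_zero_fcs(self):
        # distinct Fourier harmonics have exactly zero pairwise correlation
        t = 64
        time = np.arange(t)
        series = np.array([np.sin(2 * np.pi * k * time / t) for k in range(1, 7)])
        bold = _bold_from_series(series)
        fmap = compute_fcs(bold, _full_mask(bold), r_threshold=0.2)
        assert np.allclose(fmap.values, 0.0)

    def test_single_voxel_mask_rejected(self):
        bold = _bold_from_series(np.random.default_rng(0).standard_normal((3, 30)))
        mask = GMMask(
            np.array([[[True]], [[False]], [[False]]]), np.ones((3, 1, 1))
        )
        with pytest.raises(ValueError, match="at least 2"):
            compute_fcs(bold, mask)

    @pytest.mark.parametrize("mode", ["zsum", "rsum", "count"])
    def test_matches_brute_force_oracle(self, mode):
        rng = np.random.default_rng(1)
        series = rng.standard_normal((30, 60))
        bold = _bold_from_series(series)
        fmap = compute_fcs(bold, _full_mask(bold), r_threshold=0.2, mode=mode)
        expected = brute_force_fcs(series, 0.2, mode)
        assert np.abs(fmap.values[:, 0, 0] - expected).max() < 1e-10

    def test_block_size_does_not_change_result(self):
        rng = np.random.default_rng(2)
        series = rng.standard_normal((25, 40))
        bold = _bold_from_series(series)
        a = compute_fcs(bold, _full_mask(bold), block_size=1024)
        b = compute_fcs(bold, _full_mask(bold), block_size=7)
        assert np.abs(a.values - b.values).max() < 1e-10

    def test_threshold_monotonicity(self):
        # lowering the r threshold never decreases any voxel's FCS
        rng = np.random.default_rng(3)
        series = rng.standard_normal((20, 50))
        bold = _bold_from_series(series)
        maps = {
            thr: compute_fcs(bold, _full_mask(bold), r_threshold=thr).values
            for thr in (0.1, 0.2, 0.3)
        }
        assert (maps[0.1] >= maps[0.2] - 1e-12).all()
        assert (maps[0.2] >= maps[0.3] - 1e-12).all()

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(4)
        series = rng.standard_normal((15, 40))
        perm = rng.permutation(15)
        a = compute_fcs(_bold_from_series(series), _full_mask(_bold_from_series(series)))
        b = compute_fcs(
            _bold_from_series(series[perm]),
            _full_mask(_bold_from_series(series[perm])),
        )
        assert np.allclose(a.values[perm, 0, 0], b.values[:, 0, 0])

    def test_scale_invariance(self):
        rng = np.random.default_rng(5)
        series = rng.standard_normal((12, 40))
        scaled = series.copy()
        scaled[3] *= 17.5
        a = compute_fcs(_bold_from_series(series), _full_mask(_bold_from_series(series)))
        b = compute_fcs(_bold_from_series(scaled), _full_mask(_bold_from_series(scaled)))
        assert np.allclose(a.values, b.values)

    def test_zero_variance_voxel_dropped_not_fatal(self):
        rng = np.random.default_rng(6)
        series = rng.standard_normal((10, 40))
        series[4] = 3.0  # constant
        bold = _bold_from_series(series)
        fmap = compute_fcs(bold, _full_mask(bold))
        assert fmap.n_dropped_voxels == 1
        assert fmap.values[4, 0, 0] == 0.0

    def test_values_nonnegative_and_zero_outside_mask(self, small_fcs_maps):
        for fmap in small_fcs_maps[:3]:
            assert (fmap.values >= 0).all()
            assert np.allclose(fmap.values[~fmap.mask], 0.0)

    def test_threshold_sweep_from_one_correlation_pass(self):
        rng = np.random.default_rng(7)
        series = rng.standard_normal((18, 45))
        bold = _bold_from_series(series)
        mask = _full_mask(bold)
        r, idx = pairwise_correlations(bold, mask)
        for thr in (0.1, 0.2, 0.3):
            direct = compute_fcs(bold, mask, r_threshold=thr)
            reused = fcs_from_correlations(r, idx, bold.grid_dims, mask.include, thr)
            assert np.abs(direct.values - reused.values).max() < 1e-10


class TestSeedMaps:
    def test_single_voxel_seed_returns_series_verbatim(self):
        rng = np.random.default_rng(8)
        series = rng.standard_normal((5, 30))
        bold = _bold_from_series(series)
        seed = np.zeros(bold.grid_dims, bool)
        seed[2, 0, 0] = True
        assert np.array_equal(seed_timecourse(bold, seed), series[2])

    def test_opposite_series_cancel(self):
        x = np.random.default_rng(9).standard_normal(30)
        bold = _bold_from_series(np.array([x, -x]))
        assert np.allclose(seed_timecourse(bold, np.ones(bold.grid_dims, bool)), 0.0)

    def test_mean_matches_brute_force(self):
        rng = np.random.default_rng(10)
        series = rng.standard_normal((8, 25))
        bold = _bold_from_series(series)
        seed = np.zeros(bold.grid_dims, bool)
        seed[[1, 3, 6], 0, 0] = True
        expected = (series[1] + series[3] + series[6]) / 3
        assert np.abs(seed_timecourse(bold, seed) - expected).max() < 1e-12

    def test_empty_seed_rejected(self):
        bold = _bold_from_series(np.random.default_rng(0).standard_normal((3, 20)))
        with pytest.raises(ValueError, match="empty"):
            seed_timecourse(bold, np.zeros(bold.grid_dims, bool))

    def test_self_correlation_maps_to_clipped_maximum(self):
        rng = np.random.default_rng(11)
        series = rng.standard_normal((4, 30))
        bold = _bold_from_series(series)
        fc = seed_fc_map(bold, series[0], _full_mask(bold))
        assert fc.values[0, 0, 0] == pytest.approx(np.arctanh(MAX_ABS_R))

    def test_orthogonal_voxel_maps_to_zero(self):
        t = 64
        time = np.arange(t)
        series = np.array(
            [np.sin(2 * np.pi * time / t), np.cos(2 * np.pi * 2 * time / t)]
        )
        bold = _bold_from_series(series)
        fc = seed_fc_map(bold, series[0], _full_mask(bold))
        assert abs(fc.values[1, 0, 0]) < 1e-10

    def test_matches_per_voxel_correlation_oracle(self):
        rng = np.random.default_rng(12)
        series = rng.standard_normal((30, 60))
        seed_series = rng.standard_normal(60)
        bold = _bold_from_series(series)
        fc = seed_fc_map(bold, seed_series, _full_mask(bold))
        for i in range(30):
            r = np.corrcoef(series[i], seed_series)[0, 1]
            assert fc.values[i, 0, 0] == pytest.approx(np.arctanh(r), abs=1e-10)

    def test_zero_variance_seed_rejected(self):
        bold = _bold_from_series(np.random.default_rng(0).standard_normal((3, 20)))
        with pytest.raises(ValueError, match="zero variance"):
            seed_fc_map(bold, np.ones(20), _full_mask(bold))

    def test_positive_mask_marks_positive_z(self):
        rng = np.random.default_rng(13)
        series = rng.standard_normal((20, 40))
        bold = _bold_from_series(series)
        fc = seed_fc_map(bold, series[0], _full_mask(bold), positive_only=True)
        assert np.array_equal(fc.positive_mask, fc.values > 0)
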