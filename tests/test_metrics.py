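"""CV statistic, equal-count binning, relative CV, fits and correlations."""

import warnings

import numpy as np
import pytest

from cortivasc.metrics import (
    CvVolume,
    FmriSeries,
    StratifiedCurve,
    cv_map,
    depth_profile,
    discard_initial_frames,
    equal_count_bins,
    fit_cos2,
    intersession_correlation,
    relative_cv,
    stratified_curves,
)


def series_from_array(arr, tr=1.0):
    return FmriSeries(np.asarray(arr, dtype=float), tr, np.eye(4))


class TestDiscard:
    def test_zero_is_identity(self):
        s = series_from_array(np.random.default_rng(0).random((2, 2, 2, 10)))
        assert discard_initial_frames(s, 0) is s

    @pytest.mark.parametrize("t, n, remaining", [(112, 2, 110), (197, 3, 194)])
    def test_steady_state_discard_counts(self, t, n, remaining):
        """2 frames dropped from a 3 s TR run, 3 from a 1.7 s TR run."""
        s = series_from_array(np.zeros((1, 1, 1, t)))
        assert discard_initial_frames(s, n).n_frames == remaining

    def test_discarding_all_frames_rejected(self):
        s = series_from_array(np.zeros((1, 1, 1, 5)))
        with pytest.raises(ValueError):
            discard_initial_frames(s, 5)


class TestCvMap:
    def test_constant_series_zero_cv(self):
        s = series_from_array(np.full((2, 2, 2, 10), 7.0))
        assert np.allclose(cv_map(s).cv, 0.0)

    def test_two_point_series_exact(self):
        """(1, 3) at TR 1 s: mu = 2, sample SD = sqrt(2), CV = sqrt(2)/2."""
        s = series_from_array(np.array([1.0, 3.0]).reshape(1, 1, 1, 2))
        assert cv_map(s).cv[0, 0, 0] == pytest.approx(np.sqrt(2) / 2)

    def test_sqrt_tr_scaling(self):
        a = np.array([1.0, 3.0]).reshape(1, 1, 1, 2)
        cv1 = cv_map(series_from_array(a, tr=1.0)).cv[0, 0, 0]
        cv4 = cv_map(series_from_array(a, tr=4.0)).cv[0, 0, 0]
        assert cv4 == pytest.approx(cv1 / 2)

    def test_nonpositive_mean_flagged_nan(self):
        s = series_from_array(np.array([-1.0, 1.0]).reshape(1, 1, 1, 2))
        assert np.isnan(cv_map(s).cv[0, 0, 0])

    def test_single_frame_rejected(self):
        with pytest.raises(ValueError):
            cv_map(series_from_array(np.zeros((1, 1, 1, 1))))


class TestEqualCountBins:
    def test_six_values_three_bins(self):
        bins = equal_count_bins([10, 20, 30, 40, 50, 60], 3)
        assert np.array_equal(bins.counts, [2, 2, 2])
        assert np.allclose(bins.theta_mean, [15, 35, 55])

    def test_matches_full_sort_quantile_oracle(self):
        """Counts within +-1 of N/n and bin order = sort order, against a
        naive argsort/array_split oracle on sine-distributed angles."""
        rng = np.random.default_rng(12)
        theta = np.degrees(np.arccos(rng.random(100_000)))
        n_bins = 15
        bins = equal_count_bins(theta, n_bins)
        assert bins.counts.max() - bins.counts.min() <= 1
        # oracle: sort fully, cut at the quantile positions ceil(k*N/n)
        s = np.sort(theta, kind="stable")
        cuts = [-((-k * s.size) // n_bins) for k in range(n_bins + 1)]
        oracle_means = [s[a:b].mean() for a, b in zip(cuts[:-1], cuts[1:])]
        assert np.allclose(bins.theta_mean, oracle_means, atol=1e-9)

    def test_one_value_per_bin_limit(self):
        vals = [5.0, 1.0, 3.0]
        bins = equal_count_bins(vals, 3)
        assert np.array_equal(bins.counts, [1, 1, 1])
        assert np.allclose(bins.theta_mean, [1, 3, 5])

    def test_massive_ties_warn_but_stay_balanced(self):
        with pytest.warns(UserWarning, match="tied"):
            bins = equal_count_bins(np.zeros(100), 4)
        assert bins.counts.max() - bins.counts.min() <= 1

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            equal_count_bins([1.0], 2)


class TestRelativeCv:
    def curve(self, theta, cv):
        return StratifiedCurve("ribbon", np.asarray(theta, float), np.asarray(cv, float),
                               np.ones(len(theta), int))

    def test_arithmetic_case(self):
        out = relative_cv(self.curve([10, 88], [1.5, 1.0]))
        assert out.cv_rel_pct[0] == pytest.approx(50.0)
        assert out.cv_rel_pct[1] == 0.0

    def test_reference_bin_exactly_zero(self):
        out = relative_cv(self.curve([10, 50, 89], [1.2, 1.1, 0.9]))
        assert out.cv_rel_pct[np.argmax(out.theta_mean_deg)] == 0.0

    def test_flat_curve_all_zero(self):
        out = relative_cv(self.curve([10, 50, 89], [1.0, 1.0, 1.0]))
        assert np.allclose(out.cv_rel_pct, 0.0)

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError, match="reference"):
            relative_cv(self.curve([10, 89], [1.0, 0.0]))


def synthetic_volumes(shape=(16, 16, 16), seed=0, law="flat"):
    """CV/theta/depth volumes with a known per-voxel law for oracle checks."""
    rng = np.random.default_rng(seed)
    theta = rng.uniform(0, 90, shape).astype(np.float32)
    depth = rng.integers(1, 6, shape).astype(np.int8)
    if law == "flat":
        cv = np.ones(shape)
    else:  # cos^2 law in depth 1 only
        cv = np.where(depth == 1, 1.0 + np.cos(np.deg2rad(theta)) ** 2, 1.0)
    from cortivasc.depths import DepthVolume
    from cortivasc.surfaces import OrientationVolume

    cv_vol = CvVolume(cv, np.ones(shape), np.ones(shape), 1.0, np.eye(4))
    return cv_vol, OrientationVolume(theta, np.eye(4)), DepthVolume(depth, np.eye(4), 5)


class TestStratifiedCurves:
    def test_flat_cv_gives_zero_relative_everywhere(self):
        cv_vol, theta, depth = synthetic_volumes(law="flat")
        curves = stratified_curves(cv_vol, theta, depth, n_bins=8)
        for curve in curves.values():
            assert np.allclose(curve.cv_rel_pct, 0.0)

    def test_depth1_only_orientation_effect(self):
        """cos^2 law injected in depth 1 only: depth-1 curve rises to ~100%
        toward theta 0, depth-5 curve stays flat."""
        cv_vol, theta, depth = synthetic_volumes(law="depth1", shape=(24, 24, 24))
        curves = stratified_curves(cv_vol, theta, depth, n_bins=8)
        d1 = curves["depth_1"]
        assert d1.cv_rel_pct[0] == pytest.approx(
            100 * (1 + np.cos(np.deg2rad(d1.theta_mean_deg[0])) ** 2
                   - (1 + np.cos(np.deg2rad(d1.theta_mean_deg[-1])) ** 2))
            / (1 + np.cos(np.deg2rad(d1.theta_mean_deg[-1])) ** 2),
            rel=0.05,
        )
        assert np.allclose(curves["depth_5"].cv_rel_pct, 0.0)

    def test_bin_counts_equal_within_stratum(self):
        cv_vol, theta, depth = synthetic_volumes()
        curves = stratified_curves(cv_vol, theta, depth, n_bins=8)
        for curve in curves.values():
            assert curve.n_voxels.max() - curve.n_voxels.min() <= 1

    def test_matches_naive_groupby_oracle(self):
        """Stratified means equal an explicit per-voxel group-by loop."""
        cv_vol, theta, depth = synthetic_volumes(law="depth1")
        curves = stratified_curves(cv_vol, theta, depth, n_bins=5)
        mask = depth.data == 2
        th = theta.data[mask]
        cvv = cv_vol.cv[mask]
        order = np.argsort(th, kind="stable")
        n = len(th)
        means = []
        theta_means = []
        for b in range(5):
            sel = order[(np.arange(n) * 5) // n == b]
            means.append(cvv[sel].mean())
            theta_means.append(th[sel].mean())
        assert np.allclose(curves["depth_2"].cv_mean, means)
        assert np.allclose(curves["depth_2"].theta_mean_deg, theta_means)

    def test_small_stratum_skipped_with_warning(self):
        cv_vol, theta, depth = synthetic_volumes(shape=(4, 4, 4))
        depth.data[:] = 1
        depth.data[0, 0, 0] = 2
        with pytest.warns(UserWarning, match="skipped"):
            curves = stratified_curves(cv_vol, theta, depth, n_bins=8)
        assert "depth_2" not in curves

    def test_global_rescaling_invariance(self):
        """Multiplying the time series by c > 0 leaves CV and CV_rel unchanged."""
        rng = np.random.default_rng(3)
        data = rng.random((6, 6, 6, 40)) + 1.0
        cv_a = cv_map(series_from_array(data))
        cv_b = cv_map(series_from_array(3.7 * data))
        assert np.allclose(cv_a.cv, cv_b.cv)


class TestDepthProfile:
    def test_depth_independent_input_flat(self):
        cv_vol, theta, depth = synthetic_volumes(law="flat")
        prof = depth_profile(cv_vol, theta, depth, n_theta_groups=4)
        assert np.allclose(prof["cv_rel_pct"].dropna(), 0.0)

    def test_sigma_excess_in_depth1_recovered(self):
        """sigma multiplied by 1.5 in depth 1 with constant mu shows as
        +50% relative CV at depth 1."""
        shape = (16, 16, 16)
        cv_vol, theta, depth = synthetic_volumes(shape=shape)
        sigma = np.where(depth.data == 1, 1.5, 1.0)
        cv_vol = CvVolume(sigma.copy(), np.ones(shape), sigma, 1.0, np.eye(4))
        prof = depth_profile(cv_vol, theta, depth, n_theta_groups=4)
        d1 = prof[prof.depth == 1]
        assert np.allclose(d1["cv_rel_pct"], 50.0)
        assert np.allclose(d1["sigma_rel_pct"], 50.0)
        assert np.allclose(d1["mu_rel_pct"], 0.0)

    def test_self_normalization_is_zero(self):
        cv_vol, theta, depth = synthetic_volumes(law="depth1")
        for ref in (1, 3, 5):
            prof = depth_profile(cv_vol, theta, depth, n_theta_groups=3, normalize_to=ref)
            at_ref = prof[prof.depth == ref]
            assert np.allclose(at_ref["cv_rel_pct"].dropna(), 0.0)


class TestFitCos2:
    def noiseless_curve(self, amplitude=3.0, phase=0.0):
        theta = np.arange(0.0, 91.0, 5.0)
        cv = amplitude * np.cos(np.deg2rad(theta + phase)) ** 2
        return StratifiedCurve("ribbon", theta, cv, np.ones(theta.size, int))

    def test_recovers_noiseless_parameters(self):
        fit = fit_cos2(self.noiseless_curve(3.0, 0.0))
        assert fit.amplitude == pytest.approx(3.0, abs=1e-6)
        assert fit.phase_deg == pytest.approx(0.0, abs=1e-6)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-9)

    def test_recovers_shifted_phase(self):
        """A curve generated with theta - 10 deg fits with C = -10 deg."""
        fit = fit_cos2(self.noiseless_curve(3.0, -10.0))
        assert fit.phase_deg == pytest.approx(-10.0, abs=1e-5)

    def test_flat_curve_amplitude_near_zero_with_offset(self):
        theta = np.arange(0.0, 91.0, 10.0)
        curve = StratifiedCurve("ribbon", theta, np.full(theta.size, 2.0), np.ones(theta.size, int))
        fit = fit_cos2(curve, include_offset=True)
        assert abs(fit.amplitude) < 1e-6
        assert fit.offset == pytest.approx(2.0, abs=1e-6)

    def test_too_few_bins_rejected(self):
        curve = StratifiedCurve("ribbon", np.array([0.0, 45.0, 90.0]),
                                np.array([1.0, 0.5, 0.0]), np.ones(3, int))
        with pytest.raises(ValueError):
            fit_cos2(curve)


class TestIntersessionCorrelation:
    def curve(self, cv):
        cv = np.asarray(cv, float)
        theta = np.linspace(5, 88, cv.size)
        return StratifiedCurve("ribbon", theta, cv, np.ones(cv.size, int))

    def test_identical_curves(self):
        c = self.curve([1.0, 2.0, 3.0, 2.5])
        assert intersession_correlation(c, c) == pytest.approx(1.0)

    def test_negated_curve(self):
        a = np.array([1.0, 2.0, 3.0, 2.5])
        c = self.curve(a)
        neg = self.curve(2 * a.mean() - a)
        assert intersession_correlation(c, neg) == pytest.approx(-1.0)

    def test_zero_variance_is_nan(self):
        a = self.curve([1.0, 1.0, 1.0])
        b = self.curve([1.0, 2.0, 3.0])
        assert np.isnan(intersession_correlation(a, b))

    def test_bin_count_mismatch_rejected(self):
        with pytest.raises(ValueError):
            intersession_correlation(self.curve([1, 2, 3]), self.curve([1, 2, 3, 4]))
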