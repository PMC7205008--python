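"""Deconvolution stage: scaling, censoring, design, fit, segment areas."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st_h

from boldsense import hrf, synthetic as syn
from boldsense.errors import ConfigError, DesignError, QCError


def _flat_series(values_1d, tr=4.0, onsets=(12.0,), baseline=12.0):
    """Single-voxel BoldSeries helper."""
    n = len(values_1d)
    vals = np.asarray(values_1d, dtype=float).reshape(1, 1, 1, n)
    motion = pd.DataFrame(np.zeros((n, 6)), columns=list(hrf.MOTION_COLUMNS))
    return hrf.BoldSeries(
        values=vals, tr=tr, block_onsets=np.asarray(onsets), motion=motion,
        baseline_window=baseline,
    )


class TestScaling:
    def test_constant_series_scales_to_zero(self):
        s = _flat_series([100.0] * 20)
        assert np.allclose(hrf.scale_to_percent_change(s), 0.0)

    def test_two_percent_above_baseline(self):
        vals = [100.0] * 3 + [102.0] * 17
        out = hrf.scale_to_percent_change(_flat_series(vals))
        assert np.allclose(out[0, 0, 0, 3:], 2.0)
        assert np.allclose(out[0, 0, 0, :3], 0.0)

    def test_matches_two_pass_oracle(self, rng):
        vals = 500.0 + 30.0 * rng.random((2, 2, 2, 24))
        motion = pd.DataFrame(np.zeros((24, 6)), columns=list(hrf.MOTION_COLUMNS))
        s = hrf.BoldSeries(vals, 4.0, np.array([12.0]), motion)
        out = hrf.scale_to_percent_change(s)
        bmean = vals[..., :3].mean(axis=-1, keepdims=True)
        oracle = 100.0 * (vals - bmean) / bmean
        assert np.allclose(out, oracle, atol=1e-12)

    def test_zero_baseline_voxel_flagged_nan(self):
        vals = np.ones((2, 1, 1, 10))
        vals[1] = 0.0
        motion = pd.DataFrame(np.zeros((10, 6)), columns=list(hrf.MOTION_COLUMNS))
        s = hrf.BoldSeries(vals, 4.0, np.array([12.0]), motion)
        out = hrf.scale_to_percent_change(s)
        assert np.all(np.isnan(out[1]))
        assert np.all(np.isfinite(out[0]))


class TestCensoring:
    def test_no_motion_keeps_all(self):
        assert hrf.censor_volumes(np.zeros(10)).all()

    def test_single_volume_above_threshold_dropped(self):
        params = np.zeros((5, 6))
        params[3, 0] = 0.31  # backward diff 0.31 at volume 3, -0.31 at 4
        table = pd.DataFrame(params, columns=list(hrf.MOTION_COLUMNS))
        fd = hrf.framewise_displacement(table)
        keep = hrf.censor_volumes(fd, 0.3)
        assert list(np.flatnonzero(~keep)) == [3, 4]
        keep2 = hrf.censor_volumes(np.array([0.0, 0.1, 0.31, 0.2]), 0.3)
        assert list(np.flatnonzero(~keep2)) == [2]

    def test_matches_bruteforce_filter(self, rng):
        fd = rng.random(50)
        keep = hrf.censor_volumes(fd, 0.5)
        assert set(np.flatnonzero(keep)) == {i for i, v in enumerate(fd) if v <= 0.5}

    def test_empty_keep_set_rejected(self):
        with pytest.raises(QCError):
            hrf.censor_volumes(np.full(5, 9.0), 0.3)

    def test_rotations_converted_on_sphere(self):
        params = np.zeros((3, 6))
        params[1, 3] = 0.01  # rad -> 0.5 mm on 50 mm sphere
        fd = hrf.framewise_displacement(
            pd.DataFrame(params, columns=list(hrf.MOTION_COLUMNS))
        )
        assert np.isclose(fd[1], 0.5)


class TestDesign:
    def test_default_basis_has_13_knots(self):
        basis = hrf.TentBasis.default()
        assert basis.n_knots == 13
        assert basis.span == (-4.0, 44.0)
        assert basis.spacing == 4.0

    def test_tent_is_one_at_own_knot_zero_at_neighbors(self):
        basis = hrf.TentBasis.default()
        t = np.array([20.0 + 12.0])  # knot 20 relative to onset 12
        X = hrf.tent_design(basis, np.array([12.0]), t)
        k = list(basis.knot_times).index(20.0)
        assert X[0, k] == 1.0
        assert X[0, k - 1] == 0.0 and X[0, k + 1] == 0.0

    def test_forward_simulation_recovery(self, rng):
        """Noiseless series built from known knot amplitudes is refit exactly."""
        basis = hrf.TentBasis.default()
        onsets = np.array([12.0, 80.0, 148.0])
        times = np.arange(0.0, 220.0, 4.0)
        truth = rng.normal(size=(basis.n_knots, 7))
        truth[:2] = 0.0  # causal responses
        X, nb = hrf.build_design(basis, onsets, times, drift_order=2)
        Y = X[:, :nb] @ truth
        est = hrf.deconvolve(Y, X, nb, basis)
        assert np.allclose(est.coefficients, truth, atol=1e-8)

    def test_rank_deficiency_reported(self):
        basis = hrf.TentBasis.default()
        times = np.arange(0.0, 40.0, 4.0)  # too short to span all knots
        with pytest.raises(DesignError, match="rank"):
            hrf.build_design(basis, np.array([12.0]), times, drift_order=0)

    def test_nonmonotone_times_rejected(self):
        basis = hrf.TentBasis.default()
        with pytest.raises(DesignError):
            hrf.build_design(basis, np.array([0.0]), np.array([0.0, 4.0, 4.0]))


class TestDeconvolve:
    def test_pure_drift_gives_zero_knot_coefficients(self):
        basis = hrf.TentBasis.default()
        times = np.arange(0.0, 240.0, 4.0)
        X, nb = hrf.build_design(basis, np.array([12.0, 120.0]), times, drift_order=2)
        u = np.linspace(-1, 1, times.size)
        Y = np.column_stack([2.0 + 0.5 * u, 1.0 - 0.3 * u**2])
        est = hrf.deconvolve(Y, X, nb, basis)
        assert np.all(np.abs(est.coefficients) < 1e-8)

    def test_matches_normal_equations_oracle(self, rng):
        basis = hrf.TentBasis.default()
        times = np.arange(0.0, 240.0, 4.0)
        X, nb = hrf.build_design(basis, np.array([12.0, 120.0]), times, drift_order=1)
        Y = rng.normal(size=(times.size, 5))
        est = hrf.deconvolve(Y, X, nb, basis)
        oracle = np.linalg.solve(X.T @ X, X.T @ Y)[:nb]
        assert np.allclose(est.coefficients, oracle, atol=1e-10)

    def test_linearity_in_data(self, rng):
        basis = hrf.TentBasis.default()
        times = np.arange(0.0, 240.0, 4.0)
        X, nb = hrf.build_design(basis, np.array([12.0]), times, drift_order=1)
        Y = rng.normal(size=(times.size, 3))
        c1 = hrf.deconvolve(Y, X, nb, basis).coefficients
        c2 = hrf.deconvolve(2.0 * Y, X, nb, basis).coefficients
        assert np.allclose(c2, 2.0 * c1, atol=1e-10)


class TestSegmentAuc:
    def _estimate(self, coeffs):
        basis = hrf.TentBasis.default()
        return hrf.HrfEstimate(np.asarray(coeffs, dtype=float), basis, 0)

    def test_constant_response_integrates_to_duration(self):
        est = self._estimate(np.ones((13, 1)))
        seg1 = hrf.standard_segments()[1]
        assert np.isclose(hrf.segment_auc(est, seg1)[0], 16.0)

    def test_zero_response_zero_area(self):
        est = self._estimate(np.zeros((13, 2)))
        for seg in hrf.standard_segments().values():
            assert np.allclose(hrf.segment_auc(est, seg), 0.0)

    def test_matches_fine_grid_quadrature(self, rng):
        est = self._estimate(rng.normal(size=(13, 4)))
        t = np.arange(16.0, 32.0 + 1e-9, 0.001)
        fine = est.basis.interpolate(est.coefficients, t)
        oracle = np.trapezoid(fine, t, axis=0)
        seg2 = hrf.standard_segments()[2]
        assert np.allclose(hrf.segment_auc(est, seg2), oracle, atol=1e-9)

    def test_segments_are_additive(self, rng):
        est = self._estimate(rng.normal(size=(13, 6)))
        segs = hrf.standard_segments()
        total = sum(hrf.segment_auc(est, segs[i]) for i in (1, 2, 3))
        assert np.allclose(total, hrf.segment_auc(est, segs["full"]), atol=1e-9)

    def test_out_of_span_segment_rejected(self):
        est = self._estimate(np.zeros((13, 1)))
        with pytest.raises(ConfigError):
            hrf.segment_auc(est, hrf.SegmentDef(9, 40.0, 60.0))


class TestZTransform:
    def test_standardizes_to_mean_zero_sd_one(self, rng):
        mask = np.ones((5, 5, 4), dtype=bool)
        z = hrf.z_transform(rng.normal(2.0, 3.0, mask.shape), mask,
                            hrf.standard_segments()[1])
        assert abs(z.values.mean()) < 1e-10
        assert abs(z.values.std(ddof=1) - 1.0) < 1e-10

    def test_constant_map_rejected(self):
        mask = np.ones((4, 4, 4), dtype=bool)
        with pytest.raises(ConfigError):
            hrf.z_transform(np.full(mask.shape, 7.0), mask, hrf.standard_segments()[1])

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(
        loc=st_h.floats(-50, 50),
        scale=st_h.floats(0.1, 40),
        seed=st_h.integers(0, 2**16),
    )
    def test_affine_invariance_preserves_skewness(self, loc, scale, seed):
        """z-transform output (hence its skewness) ignores location/scale."""
        mask = np.ones((4, 4, 3), dtype=bool)
        base = np.random.default_rng(seed).normal(size=mask.shape)
        seg = hrf.standard_segments()[1]
        z0 = hrf.z_transform(base, mask, seg).values
        z1 = hrf.z_transform(loc + scale * base, mask, seg).values
        assert np.allclose(z0, z1, atol=1e-8)


class TestEndToEndRecovery:
    def test_noiseless_cohort_recovers_truth_at_knots_and_areas(self, noiseless_cohort):
        co = noiseless_cohort
        segs = hrf.standard_segments()
        for s in co.subjects[:2]:
            scaled = hrf.scale_to_percent_change(s.bold)
            keep = hrf.censor_volumes(s.bold.motion, 0.3)
            X, nb = hrf.build_design(
                co.basis, s.bold.block_onsets, s.bold.volume_times,
                run_starts=s.bold.run_starts, tr=co.config.tr,
            )
            est = hrf.deconvolve(scaled[co.mask].T, X, nb, co.basis, keep=keep)
            truth = np.outer(co.shape_knots, s.amplitude_true[co.mask])
            assert np.allclose(est.coefficients, truth, atol=1e-6)
            for key in (1, 2, 3, "full"):
                auc = hrf.segment_auc(est, segs[key])
                assert np.allclose(auc, co.true_segment_auc(s, segs[key]), atol=1e-6)
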