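"""Evaluation statistics: accuracy, correlations, LOO, power, clusters."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from boldsense import stats as st
from boldsense.errors import ConfigError, GridError
from boldsense.grid import VolumeGrid


def _trials(correct_by_trial, subject="sub-01", n_runs=3, n_blocks=6):
    """Trial table with a fixed correctness value per trial index."""
    rows = []
    for run in range(1, n_runs + 1):
        for block in range(1, n_blocks + 1):
            for trial in range(1, 9):
                rows.append(
                    {"subject": subject, "run": run, "block": block,
                     "trial_index": trial, "correct": correct_by_trial[trial - 1]}
                )
    return pd.DataFrame(rows)


class TestSegmentAccuracy:
    def test_all_correct_is_100(self):
        recs = st.segment_accuracy(_trials([1] * 8), 1)
        assert recs[0].accuracy == 100.0
        assert recs[0].n_trials == 72  # 4 words x 6 blocks x 3 runs

    def test_half_correct_is_50(self):
        # trials 5, 6 correct; 7, 8 incorrect -> Seg2 = 36/72
        recs = st.segment_accuracy(_trials([0, 0, 0, 0, 1, 1, 0, 0]), 2)
        assert recs[0].n_correct == 36
        assert recs[0].accuracy == 50.0

    def test_matches_bruteforce_count(self, rng):
        table = _trials([1] * 8)
        table["correct"] = rng.integers(0, 2, len(table))
        for seg, sel in ((1, table.trial_index <= 4), (2, table.trial_index > 4)):
            recs = st.segment_accuracy(table, seg)
            assert recs[0].n_correct == int(table.loc[sel, "correct"].sum())
            assert recs[0].n_trials == int(sel.sum())

    def test_flagged_missing_reduces_denominator(self):
        table = _trials([1] * 8)
        table.loc[table.index[:2], "correct"] = np.nan  # two Seg1 trials missing
        recs = st.segment_accuracy(table, 1)
        assert recs[0].n_trials == 70

    def test_absent_rows_count_incorrect_with_expected_total(self):
        table = _trials([1] * 8)
        table = table[~((table.run == 1) & (table.block == 1) & (table.trial_index == 1))]
        recs = st.segment_accuracy(table, 1, expected_total=72)
        assert recs[0].n_correct == 71
        assert recs[0].n_trials == 72


class TestPointBiserial:
    def test_identical_values_give_zero_r(self):
        with pytest.raises(ConfigError):
            st.point_biserial(np.array([0, 0, 1, 1]), np.array([2.0, 2.0, 2.0, 2.0]))
        out = st.point_biserial(np.array([0, 0, 1, 1, 1]),
                                np.array([1.0, 3.0, 2.0, 2.0, 2.0]))
        assert abs(out.r) < 1

    def test_perfect_separation_gives_unit_r(self):
        out = st.point_biserial(np.array([0, 0, 1, 1]), np.array([1.0, 1.0, 2.0, 2.0]))
        assert np.isclose(abs(out.r), 1.0)

    def test_equals_two_sample_t(self, rng):
        g = rng.integers(0, 2, 30)
        g[:3] = 0
        g[-3:] = 1
        v = rng.normal(size=30) + 0.5 * g
        out = st.point_biserial(g, v)
        t2, _ = sps.ttest_ind(v[g == 1], v[g == 0], equal_var=True)
        assert np.isclose(abs(out.t), abs(t2), atol=1e-10)


class TestRegressionSummaries:
    def test_collinear_data_r2_one(self):
        out = st.bold_behavior_regression(np.arange(6.0), 3.0 + 2.0 * np.arange(6.0))
        assert np.isclose(out.r2, 1.0)

    def test_orthogonal_data_r2_zero(self):
        x = np.array([-1.0, 1.0, -1.0, 1.0])
        y = np.array([1.0, 1.0, -1.0, -1.0])
        assert st.bold_behavior_regression(x, y).r2 < 1e-12

    def test_internal_r_t_p_consistency(self, rng):
        for _ in range(20):
            x = rng.normal(size=15)
            y = 0.4 * x + rng.normal(size=15)
            out = st.bold_behavior_regression(x, y)
            t_expected = out.r * np.sqrt(out.n - 2) / np.sqrt(1 - out.r**2)
            p_expected = 2 * sps.t.sf(abs(t_expected), out.n - 2)
            assert np.isclose(out.t, t_expected, atol=1e-10)
            assert np.isclose(out.p, p_expected, atol=1e-10)
            assert np.isclose(out.r2, out.r**2, atol=1e-12)

    @pytest.mark.parametrize(
        "alpha,m,expected", [(0.01, 3, 0.01 / 3), (0.1, 3, 0.1 / 3), (0.05, 1, 0.05)]
    )
    def test_bonferroni(self, alpha, m, expected):
        assert np.isclose(st.bonferroni(alpha, m), expected)

    @pytest.mark.parametrize(
        "r2_red,r2_full,expected",
        [(0.35, 0.48, 0.25), (0.28, 0.30, 0.03), (0.06, 0.12, 0.07), (0.4, 0.4, 0.0)],
    )
    def test_cohens_f2(self, r2_red, r2_full, expected):
        assert round(st.cohens_f2(r2_red, r2_full), 2) == expected

    def test_fisher_z(self):
        assert st.fisher_z(0.0) == 0.0
        assert np.isclose(st.fisher_z(0.5), 0.5493, atol=1e-4)
        r = 0.731
        assert np.isclose(np.tanh(st.fisher_z(r)), r, atol=1e-12)
        with pytest.raises(ConfigError):
            st.fisher_z(1.0)


class TestLoo:
    def test_perfect_linear_data_zero_errors(self):
        c = np.linspace(40, 70, 8)
        z = 0.2 - 0.01 * c
        cv = st.loo_cv(z, c)
        assert np.allclose(cv.cve, 0.0, atol=1e-20)
        assert np.allclose(cv.pe, 0.0, atol=1e-8)

    def test_stated_error_formulas(self):
        # a fold with obs 2 and pred 1 contributes cve 1 and PE 50%
        obs, pred = 2.0, 1.0
        assert (obs - pred) ** 2 == 1.0
        assert 100.0 * (obs - pred) / obs == 50.0
        # and the implementation reproduces them on a constructed cohort
        c = np.array([10.0, 20.0, 30.0, 40.0, 25.0])
        z = 0.1 * c
        z[-1] += 1.0  # held-out subject deviates by ~1 from the others' fit
        cv = st.loo_cv(z, c)
        assert np.isclose(cv.cve[-1], (z[-1] - 2.5) ** 2, atol=1e-10)

    def test_predictions_match_refit_oracle(self, rng):
        z = rng.normal(size=12)
        c = rng.normal(50, 8, size=12)
        cv = st.loo_cv(z, c)
        for k in range(12):
            keep = np.ones(12, bool)
            keep[k] = False
            slope, intercept, *_ = sps.linregress(c[keep], z[keep])
            assert np.isclose(cv.predictions[k], intercept + slope * c[k], atol=1e-10)

    def test_near_zero_observation_excluded_from_pe(self):
        c = np.array([10.0, 20.0, 30.0, 40.0, 50.0])
        z = np.array([1.0, -1.0, 1e-12, 1.0, -1.0])
        with pytest.warns(UserWarning, match="percent-error"):
            cv = st.loo_cv(z, c)
        assert np.isnan(cv.pe[2])
        assert np.isfinite(cv.mean_pe)

    def test_model_comparison_prefers_true_model(self):
        """When activity = neural + b*CBF and behaviour tracks the neural
        part, the covariate model's per-fold behaviour R^2 beats standard."""
        wins = 0
        for seed in range(25):
            r = np.random.default_rng(seed)
            c = r.normal(50, 10, 24)
            neural = r.normal(0, 0.25, 24)
            z = 0.3 + neural - 0.02 * c + r.normal(0, 0.05, 24)
            acc = 80 + 30 * neural + r.normal(0, 3, 24)
            comp = st.compare_models_loo(z, c, acc, models=("standard", "covariate"))
            if (comp["per_model"]["covariate"]["r2"].mean()
                    > comp["per_model"]["standard"]["r2"].mean()):
                wins += 1
        assert wins >= 20


class TestAchievedPower:
    def test_size_under_null(self):
        assert np.isclose(st.achieved_power(0.0, 1.0, 1.0, 24, 0.05), 0.05)

    def test_near_unit_correlation_near_unit_power(self):
        assert st.achieved_power(0.99, 1.0, 1.0, 24, 0.05) > 0.99

    def test_matches_monte_carlo_rejection_rate(self):
        """Bivariate-normal simulation oracle at rho = 0.5, n = 24."""
        n, rho, reps = 24, 0.5, 10000
        r = np.random.default_rng(99)
        x = r.standard_normal((reps, n))
        y = rho * x + np.sqrt(1 - rho**2) * r.standard_normal((reps, n))
        xm = x - x.mean(1, keepdims=True)
        ym = y - y.mean(1, keepdims=True)
        rr = (xm * ym).sum(1) / np.sqrt((xm**2).sum(1) * (ym**2).sum(1))
        tt = rr * np.sqrt(n - 2) / np.sqrt(1 - rr**2)
        tcrit = sps.t.ppf(0.975, n - 2)
        mc = (np.abs(tt) > tcrit).mean()
        se = np.sqrt(mc * (1 - mc) / reps)
        assert abs(st.achieved_power(rho, 1.0, 1.0, n, 0.05) - mc) < 2 * se

    def test_out_of_range_correlation_rejected(self):
        with pytest.raises(ConfigError):
            st.achieved_power(2.0, 1.0, 1.0, 24)


class TestGroupMap:
    def test_identical_groups_give_zero_t(self, rng):
        A = rng.normal(size=(6, 50))
        t, df = st.group_map(A, A.copy())
        assert np.allclose(t, 0.0)
        assert df == 10

    def test_one_sample_matches_oracle(self, rng):
        A = rng.normal(0.3, 1.0, size=(9, 40))
        t, df = st.group_map(A)
        oracle = A.mean(0) / (A.std(0, ddof=1) / np.sqrt(9))
        assert np.allclose(t, oracle, atol=1e-12)
        assert df == 8

    def test_null_p_values_uniform(self, rng):
        """Two-sample t on exchangeable groups has ~uniform p-values."""
        A = rng.normal(size=(12, 1000))
        B = rng.normal(size=(12, 1000))
        t, df = st.group_map(A, B)
        p = 2 * sps.t.sf(np.abs(t), df)
        ks = sps.kstest(p, "uniform")
        assert ks.pvalue > 0.01


class TestClusters:
    def test_two_disjoint_blobs_found_with_sizes(self):
        grid = VolumeGrid((10, 10, 6), (2.0, 2.0, 2.0))
        mask = np.ones(grid.shape, bool)
        tmap = np.zeros(grid.shape)
        tmap[1:3, 1:3, 1:3] = 5.0  # 8 voxels, positive
        tmap[7:9, 7:9, 2:5] = -5.0  # 12 voxels, negative
        clusters, k = st.cluster_threshold(
            tmap, mask, df=22, grid=grid, smoothness_fwhm_mm=4.0,
            extent_voxels=2,
        )
        assert len(clusters) == 2
        sizes = sorted(c.n_voxels for c in clusters)
        assert sizes == [8, 12]
        signs = {c.sign for c in clusters}
        assert signs == {"+", "-"}
        assert {c.n_voxels: c.size_mm3 for c in clusters} == {8: 64.0, 12: 96.0}

    def test_six_connectivity_separates_diagonal_voxels(self):
        grid = VolumeGrid((4, 4, 4), (1.0, 1.0, 1.0))
        mask = np.ones(grid.shape, bool)
        tmap = np.zeros(grid.shape)
        tmap[0, 0, 0] = 9.0
        tmap[1, 1, 1] = 9.0  # touches only diagonally
        clusters, _ = st.cluster_threshold(
            tmap, mask, df=20, grid=grid, smoothness_fwhm_mm=2.0, extent_voxels=1
        )
        assert len(clusters) == 2

    def test_extent_threshold_monotone_in_voxel_p(self, small_grid):
        mask = np.ones(small_grid.shape, bool)
        ks = [
            st.simulate_extent_threshold(
                mask, 4.0, small_grid, voxel_p=p, n_sims=150, seed=4
            )
            for p in (0.05, 0.01, 0.001)
        ]
        assert ks[0] >= ks[1] >= ks[2]

    def test_too_few_simulations_rejected(self, small_grid):
        with pytest.raises(ConfigError):
            st.simulate_extent_threshold(
                np.ones(small_grid.shape, bool), 4.0, small_grid, n_sims=50
            )


class TestClassification:
    def _cluster(self, voxels, label=1, sign="+"):
        return st.ClusterReport(
            label=label, voxels=np.asarray(voxels), peak_ijk=(0, 0, 0),
            peak_mm=(0.0, 0.0, 0.0), peak_stat=5.0,
            size_mm3=float(len(voxels)), sign=sign,
        )

    def test_standard_only_is_false_positive(self):
        out = st.classify_effectiveness([self._cluster([1, 2, 3])], [], (4, 4, 4))
        assert [c.classification for c in out] == ["FP"]

    def test_sensitized_only_is_false_negative(self):
        out = st.classify_effectiveness([], [self._cluster([5, 6])], (4, 4, 4))
        assert [c.classification for c in out] == ["FN"]

    def test_identical_sets_all_retained(self):
        a = [self._cluster([1, 2, 3]), self._cluster([10, 11], label=2)]
        b = [self._cluster([1, 2, 3]), self._cluster([10, 11], label=2)]
        out = st.classify_effectiveness(a, b, (4, 4, 4))
        assert all(c.classification == "R" for c in out)
        assert len(out) == 2

    def test_single_shared_voxel_counts_as_overlap(self):
        out = st.classify_effectiveness(
            [self._cluster([1, 2, 3])], [self._cluster([3, 20, 21])], (4, 4, 4)
        )
        assert [c.classification for c in out] == ["R"]

    def test_grid_mismatch_rejected(self):
        with pytest.raises(GridError):
            st.classify_effectiveness([self._cluster([100])], [], (2, 2, 2))
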