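import math

import numpy as np
import pytest
from scipy import stats
from sklearn.metrics import adjusted_rand_score

from helpers import make_matrices
from lamdec.population import (
    build_population_matrix,
    kmeans_with_gap,
    loading_uniformity_tests,
    offset_rt_correlation,
    softmax_pca,
    trial_alignment_offsets,
)
from lamdec.rates import RateMatrix, smoothed_rates
from lamdec.visuomotor import tuning_preference


class TestSoftmaxPCA:
    def test_rank_one_population(self):
        rng = np.random.default_rng(0)
        base = rng.standard_normal(120)
        rows = [a * base for a in (1.0, -2.0, 3.0, -0.5, 1.5, 2.5, -1.0, 0.75)]
        pm = build_population_matrix([r[:60] for r in rows], [r[60:] for r in rows])
        _, loadings, var_frac = softmax_pca(pm, 2)
        assert var_frac[0] > 0.999
        assert var_frac.sum() == pytest.approx(1.0)

    def test_constant_rows_dropped(self):
        rng = np.random.default_rng(1)
        rows = [rng.standard_normal(40) for _ in range(5)] + [np.zeros(40)]
        pm = build_population_matrix([r[:20] for r in rows], [r[20:] for r in rows])
        assert pm.dropped_units == [5]
        assert pm.values.shape[0] == 5

    def test_normalized_rows_have_unit_range(self):
        rng = np.random.default_rng(2)
        rows = [10 * rng.standard_normal(50) for _ in range(6)]
        pm = build_population_matrix([r[:25] for r in rows], [r[25:] for r in rows])
        assert np.allclose(np.ptp(pm.values, axis=1), 1.0)

    def test_pc1_loading_tracks_visuomotor_index(
        self, demo_session, demo_cue_matrices, demo_vm_results
    ):
        """The first principal axis of the normalized population aligns with
        the handcrafted visuomotor continuum."""
        pref, nonp, ids = [], [], []
        for m in demo_cue_matrices:
            tun = tuning_preference(demo_session.spike_times(m.unit_id),
                                    demo_session.trials, unit_id=m.unit_id)
            sel = (m.time_axis >= -100) & (m.time_axis < 600)
            with np.errstate(invalid="ignore"):
                p = np.nanmean(m.values[m.choices == tun.preferred][:, sel], axis=0)
                q = np.nanmean(m.values[m.choices == -tun.preferred][:, sel], axis=0)
            pref.append(np.nan_to_num(p))
            nonp.append(np.nan_to_num(q))
            ids.append(m.unit_id)
        pm = build_population_matrix(pref, nonp, ids)
        _, loadings, _ = softmax_pca(pm, 2)
        idx = {r.unit_id: r.index_r for r in demo_vm_results}
        iv = np.array([idx[u] for u in pm.unit_ids])
        rho = stats.spearmanr(loadings[:, 0], iv).statistic
        assert abs(rho) > 0.6  # PC sign is arbitrary


class TestLoadingUniformity:
    def test_isotropic_gaussian_calibrated(self):
        rejections = 0
        n_rep = 60
        for s in range(n_rep):
            rng = np.random.default_rng(1000 + s)
            L = rng.standard_normal((80, 2))
            _, _, p = loading_uniformity_tests(L, n_null=200, rng=rng)
            rejections += p < 0.05
        assert rejections / n_rep < 0.15

    def test_axis_concentrated_loadings_rejected(self):
        rng = np.random.default_rng(3)
        L = np.column_stack([3 * rng.standard_normal(80), 0.05 * rng.standard_normal(80)])
        chi2_p, _, pairs_p = loading_uniformity_tests(L, n_null=1000, rng=rng)
        assert chi2_p < 0.01 and pairs_p < 0.01

    def test_octant_centers_give_zero_chi2(self):
        angles = (np.arange(8) + 0.5) * (np.pi / 4)
        pts = np.repeat(np.column_stack([np.cos(angles), np.sin(angles)]), 5, axis=0)
        chi2_p, _, _ = loading_uniformity_tests(pts, n_null=100, rng=0)
        assert chi2_p == pytest.approx(1.0)

    def test_too_few_units_skips_octant_test(self):
        rng = np.random.default_rng(4)
        chi2_p, _, _ = loading_uniformity_tests(rng.standard_normal((12, 2)),
                                                n_null=100, rng=rng)
        assert math.isnan(chi2_p)


class TestGapStatistic:
    def test_three_separated_clusters(self):
        hits = 0
        for s in range(15):
            rng = np.random.default_rng(s)
            X = np.vstack([c + rng.standard_normal((30, 2))
                           for c in ([0, 0], [8, 0], [0, 8])])
            k, labels = kmeans_with_gap(X, range(1, 7), B_reference=50, rng=rng)
            hits += k == 3
        assert hits >= 14

    def test_single_blob_gives_one_cluster(self):
        rng = np.random.default_rng(30)
        k, labels = kmeans_with_gap(rng.standard_normal((90, 2)), range(1, 7), rng=rng)
        assert k == 1
        assert np.all(labels == 0)

    def test_row_permutation_invariance_up_to_relabel(self):
        rng = np.random.default_rng(31)
        X = np.vstack([c + rng.standard_normal((30, 2)) for c in ([0, 0], [9, 0], [0, 9])])
        k1, lab1 = kmeans_with_gap(X, range(2, 5), rng=1)
        perm = rng.permutation(X.shape[0])
        k2, lab2 = kmeans_with_gap(X[perm], range(2, 5), rng=2)
        assert k1 == k2 == 3
        assert adjusted_rand_score(lab1[perm], lab2) == pytest.approx(1.0)


class TestAlignmentOffsets:
    def _template_matrix(self, rng, lags, noise_sd=2.0, n_bins=800):
        t = np.arange(n_bins)
        tmpl = 20 * np.exp(-0.5 * ((t - n_bins / 2) / 60.0) ** 2)
        vals = np.array([np.roll(tmpl, L) for L in lags])
        vals = vals + noise_sd * rng.standard_normal(vals.shape)
        n = len(lags)
        return RateMatrix(0, "move", np.arange(-n_bins // 2, n_bins // 2), vals, 50,
                          np.arange(n), np.full(n, 500), np.full(n, 12.0),
                          np.ones(n, dtype=int))

    def test_identical_trials_zero_offsets(self):
        rng = np.random.default_rng(5)
        m = self._template_matrix(rng, np.zeros(40, dtype=int), noise_sd=0.0)
        res = trial_alignment_offsets(m, max_lag_ms=100)
        assert np.all(res.offsets_ms == 0)
        assert res.converged

    def test_injected_lags_recovered(self):
        """A trial delayed by L needs offset -L; recovery up to a common
        additive constant with RMSE well under the boxcar width."""
        rng = np.random.default_rng(6)
        lags = rng.integers(-80, 81, 50)
        m = self._template_matrix(rng, lags)
        res = trial_alignment_offsets(m, max_lag_ms=150)
        err = res.offsets_ms + lags
        err = err - err.mean()
        assert np.sqrt(np.mean(err**2)) <= 50.0

    def test_pure_noise_converges_with_bounded_offsets(self):
        rng = np.random.default_rng(7)
        m = self._template_matrix(rng, np.zeros(40, dtype=int), noise_sd=10.0)
        m.values = 10.0 * rng.standard_normal(m.values.shape)
        res = trial_alignment_offsets(m, max_lag_ms=120)
        assert np.all(np.abs(res.offsets_ms) <= 120)
        assert res.n_iterations <= 25

    def test_too_few_trials_rejected(self):
        rng = np.random.default_rng(8)
        m = self._template_matrix(rng, np.zeros(10, dtype=int))
        with pytest.raises(ValueError):
            trial_alignment_offsets(m)


class TestOffsetRTCorrelation:
    def _unit_matrix(self, bundle, unit_id):
        return smoothed_rates(bundle.spike_times(unit_id), bundle.trials, "move", 50,
                              unit_id=unit_id)

    def test_cue_locked_units_positive_movement_locked_near_zero(
        self, demo_session, demo_move_matrices
    ):
        gt = demo_session.ground_truth
        rs = {}
        for m in demo_move_matrices:
            res = trial_alignment_offsets(m)
            r, _ = offset_rt_correlation(res, m)
            rs.setdefault(gt[m.unit_id], []).append(r)
        assert np.median(rs["increased"]) > 0.2
        assert abs(np.median(rs["perimovement"])) < np.median(rs["increased"])

    def test_sign_correction_matches_index_sign(self, demo_session, demo_move_matrices,
                                                demo_vm_results):
        """After the sign flip for decreased units, the offset correlation
        agrees in sign with the visuomotor index for both poles."""
        gt = demo_session.ground_truth
        idx = {r.unit_id: r.index_r for r in demo_vm_results}
        agree, total = 0, 0
        for m in demo_move_matrices:
            if gt[m.unit_id] == "perimovement":
                continue
            res = trial_alignment_offsets(m)
            _, rc = offset_rt_correlation(res, m)
            if math.isfinite(rc):
                agree += np.sign(rc) == np.sign(idx[m.unit_id])
                total += 1
        assert total >= 10
        assert agree >= 0.8 * total

    def test_degenerate_offsets_undefined(self):
        rng = np.random.default_rng(9)
        m = make_matrices(rng, n_units=1, n_trials=40)[0]
        from lamdec.population import AlignmentResult

        res = AlignmentResult(0, np.zeros(40), 1, True, m.rts.astype(float))
        r, rc = offset_rt_correlation(res, m)
        assert math.isnan(r) and math.isnan(rc)
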