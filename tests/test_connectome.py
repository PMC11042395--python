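"""Censoring, RSFC assembly, confound residualization and GLMs."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

import sleepcca as sc
from sleepcca.connectome import SchemaError, _simple_glm


def make_matrices(E_vectors, p):
    """Wrap upper-triangle edge vectors into ConnectivityMatrix objects."""
    iu = np.triu_indices(p, k=1)
    out = []
    for i, v in enumerate(E_vectors):
        W = np.zeros((p, p))
        W[iu] = v
        out.append(sc.ConnectivityMatrix(matrix=W + W.T,
                                         parcel_labels=[f"P{j}" for j in range(p)],
                                         subject_id=f"s{i}"))
    return out


class TestCensorMask:
    def test_clean_run_fully_kept(self):
        mask = sc.build_censor_mask(np.zeros(20), np.zeros(20))
        assert mask.keep.all() and not mask.run_excluded

    def test_single_midrun_outlier_excludes_run(self):
        """12 frames, outlier at frame 6 (1-based): dilation censors
        frames 5-8; the remaining segments (1-4, 9-12) are shorter than
        5 frames and get censored too, so the run is excluded."""
        fd = np.zeros(12)
        fd[5] = 0.5
        mask = sc.build_censor_mask(fd, np.zeros(12))
        assert not mask.keep.any()
        assert mask.run_excluded

    def test_outlier_at_first_frame_keeps_run(self):
        """Outlier at frame 1: frames 1-3 censored (no frame before
        exists), segment 4-12 (9 frames) survives; 3/12 censored."""
        fd = np.zeros(12)
        fd[0] = 0.5
        mask = sc.build_censor_mask(fd, np.zeros(12))
        np.testing.assert_array_equal(mask.keep,
                                      [False] * 3 + [True] * 9)
        assert not mask.run_excluded
        assert mask.censored_fraction == pytest.approx(3 / 12)

    def test_dvars_threshold_also_censors(self):
        dv = np.zeros(30)
        dv[10] = 100.0
        mask = sc.build_censor_mask(np.zeros(30), dv)
        assert not mask.keep[9:13].any()

    def test_empty_trace_rejected(self):
        with pytest.raises(SchemaError):
            sc.build_censor_mask([], [])

    def test_dilation_and_segment_invariants_random(self, rng):
        for _ in range(20):
            n = int(rng.integers(10, 60))
            fd = rng.uniform(0, 0.4, n)
            mask = sc.build_censor_mask(fd, np.zeros(n))
            keep = mask.keep
            # censored set closed under 1-before/2-after dilation
            for i in np.flatnonzero(fd > 0.2):
                assert not keep[max(i - 1, 0): i + 3].any()
            # every kept segment has length >= 5
            runs = np.diff(np.flatnonzero(np.diff(
                np.concatenate([[0], keep.astype(int), [0]]))))
            kept_lengths = runs[::2] if keep[0] else runs[1::2] if runs.size else []
            segs = []
            i = 0
            while i < n:
                if keep[i]:
                    j = i
                    while j < n and keep[j]:
                        j += 1
                    segs.append(j - i)
                    i = j
                else:
                    i += 1
            assert all(s >= 5 for s in segs)
            assert mask.run_excluded == (mask.censored_fraction > 0.5)


class TestComputeRSFC:
    def test_orthogonal_parcels_give_zero_z(self):
        ts = np.array([[1.0, -1.0, 1.0, -1.0, 1.0],
                       [1.0, 1.0, -1.0, -1.0, 1.0]])
        mask = sc.build_censor_mask(np.zeros(5), np.zeros(5), min_segment=1)
        m = sc.compute_rsfc([(ts[:, :4], sc.CensorMask(np.ones(4, bool), 0.2, 75, False))])
        assert m.matrix[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_run_averaging(self, rng):
        ts1 = rng.standard_normal((4, 30))
        ts2 = rng.standard_normal((4, 30))
        keep = sc.CensorMask(np.ones(30, bool), 0.2, 75, False)
        m1 = sc.compute_rsfc([(ts1, keep)])
        m2 = sc.compute_rsfc([(ts2, keep)])
        both = sc.compute_rsfc([(ts1, keep), (ts2, keep)])
        np.testing.assert_allclose(both.matrix, (m1.matrix + m2.matrix) / 2,
                                   atol=1e-12)
        assert both.n_runs_averaged == 2

    def test_censored_frames_excluded_from_correlation(self, rng):
        ts = rng.standard_normal((3, 5))
        keep = np.array([True, True, False, True, True])
        m = sc.compute_rsfc([(ts, sc.CensorMask(keep, 0.2, 75, False))])
        a, b = ts[0, keep], ts[1, keep]
        r = np.corrcoef(a, b)[0, 1]
        assert m.matrix[0, 1] == pytest.approx(np.arctanh(r), abs=1e-12)

    def test_excluded_runs_skipped_and_all_excluded_raises(self, rng):
        ts = rng.standard_normal((3, 20))
        good = sc.CensorMask(np.ones(20, bool), 0.2, 75, False)
        bad = sc.CensorMask(np.zeros(20, bool), 0.2, 75, True)
        m = sc.compute_rsfc([(ts, good), (ts, bad)])
        assert m.n_runs_averaged == 1
        with pytest.raises(SchemaError, match="all runs excluded"):
            sc.compute_rsfc([(ts, bad)])

    def test_zero_variance_parcel_rejected(self):
        ts = np.vstack([np.ones(10), np.arange(10.0)])
        keep = sc.CensorMask(np.ones(10, bool), 0.2, 75, False)
        with pytest.raises(SchemaError, match="zero-variance"):
            sc.compute_rsfc([(ts, keep)])

    def test_perfect_correlation_clipped_before_atanh(self):
        ts = np.vstack([np.arange(10.0), 2 * np.arange(10.0)])
        keep = sc.CensorMask(np.ones(10, bool), 0.2, 75, False)
        m = sc.compute_rsfc([(ts, keep)])
        assert np.isfinite(m.matrix[0, 1])
        assert m.matrix[0, 1] == pytest.approx(np.arctanh(1 - 1e-7))


class TestResidualize:
    def test_exact_multiple_of_covariate_residuals_zero(self, rng):
        age = rng.uniform(20, 40, 10)
        E = np.column_stack([2 * age, rng.standard_normal(10)])
        mats = make_matrices([[E[i, 0], E[i, 1], 0.0] for i in range(10)], 3)
        out = sc.residualize_confounds(mats, age)
        for m in out:
            assert abs(m.matrix[0, 1]) < 1e-10

    def test_orthogonal_covariate_only_demeans(self, rng):
        n = 40
        edge = rng.standard_normal(n)
        cov = rng.standard_normal(n)
        cov -= cov @ edge / (edge @ edge) * edge  # orthogonalize
        mats = make_matrices([[edge[i], 0.0, 0.0] for i in range(n)], 3)
        out = sc.residualize_confounds(mats, cov)
        got = np.array([m.matrix[0, 1] for m in out])
        expected = edge - edge.mean() - cov * np.polyfit(cov, edge, 1)[0]
        # covariate ~ orthogonal, so slope ~ 0: edge unchanged up to mean
        np.testing.assert_allclose(got, edge - edge.mean() -
                                   (np.column_stack([np.ones(n), cov]) @
                                    np.linalg.lstsq(np.column_stack([np.ones(n), cov]),
                                                    edge, rcond=None)[0] -
                                    edge.mean()), atol=1e-10)

    def test_normal_equations_oracle_n6(self):
        age = np.array([22.0, 25.0, 28.0, 31.0, 34.0, 36.0])
        sex = np.array([0.0, 1.0, 0.0, 1.0, 0.0, 1.0])
        edge = np.array([1.0, 3.0, 2.0, 5.0, 4.0, 6.0])
        Z = np.column_stack([np.ones(6), age, sex])
        beta = np.linalg.solve(Z.T @ Z, Z.T @ edge)
        expected = edge - Z @ beta
        mats = make_matrices([[edge[i], 0.0, 0.0] for i in range(6)], 3)
        out = sc.residualize_confounds(mats, np.column_stack([age, sex]))
        got = np.array([m.matrix[0, 1] for m in out])
        np.testing.assert_allclose(got, expected, atol=1e-10)

    def test_collinear_covariates_warn(self, rng):
        cov = rng.standard_normal(10)
        mats = make_matrices([[rng.standard_normal(), 0, 0] for _ in range(10)], 3)
        with pytest.warns(RuntimeWarning, match="collinear"):
            sc.residualize_confounds(mats, np.column_stack([cov, 2 * cov]))


class TestEdgewiseGLM:
    def test_noiseless_linearity_flagged_exact(self):
        score = np.array([0.5, -1.0, 2.0, 0.0, 1.0, -0.5, 3.0, 0.2])
        mats = make_matrices([[3 * s, 0.0, 0.0] for s in score], 3)
        res = sc.edgewise_glm(mats, score)
        assert res.beta[0, 1] == pytest.approx(3.0, abs=1e-12)
        assert res.exact_fit[0, 1] == 1.0
        assert res.pval[0, 1] == 0.0

    def test_matches_statsmodels_oracle(self, rng):
        n = 8
        score = rng.standard_normal(n)
        E = rng.standard_normal((n, 6))
        beta, t, F, pv, exact, df = _simple_glm(E, score)
        for j in range(6):
            fit = sm.OLS(E[:, j], sm.add_constant(score)).fit()
            assert beta[j] == pytest.approx(fit.params[1], abs=1e-10)
            assert t[j] == pytest.approx(fit.tvalues[1], abs=1e-10)
            assert F[j] == pytest.approx(fit.tvalues[1] ** 2, abs=1e-8)
            assert pv[j] == pytest.approx(fit.pvalues[1], abs=1e-10)
        assert df == n - 2

    def test_null_rejection_rate_rough(self, rng):
        n = 400
        score = rng.standard_normal(n)
        E = rng.standard_normal((n, 500))
        _, _, _, pv, _, _ = _simple_glm(E, score)
        rate = (pv < 0.05).mean()
        assert 0.02 < rate < 0.08

    def test_constant_score_rejected(self):
        mats = make_matrices([[1.0, 0, 0]] * 5, 3)
        with pytest.raises(ValueError, match="constant composite"):
            sc.edgewise_glm(mats, np.ones(5))

    def test_frisch_waugh_partial_coefficient(self, rng):
        """Beta on residualized edges equals the partial coefficient of
        the joint model with confounds included."""
        n = 60
        score = rng.standard_normal(n)
        cov = rng.standard_normal((n, 2)) + 0.3 * score[:, None]
        edge = 0.4 * score + cov @ [0.5, -0.2] + rng.standard_normal(n)
        mats = make_matrices([[edge[i], 0.0, 0.0] for i in range(n)], 3)
        resid_mats = sc.residualize_confounds(mats, cov)
        # the predictor must be residualized on the same confounds
        Z = np.column_stack([np.ones(n), cov])
        score_r = score - Z @ np.linalg.lstsq(Z, score, rcond=None)[0]
        res = sc.edgewise_glm(resid_mats, score_r)
        joint = sm.OLS(edge, sm.add_constant(np.column_stack([score, cov]))).fit()
        assert res.beta[0, 1] == pytest.approx(joint.params[1], abs=1e-10)


class TestNetworkAverage:
    def test_hand_computation_two_networks(self):
        # 4 parcels, nets A={0,1}, B={2,3}; within w1=W[0,1], w2=W[2,3]
        W = np.zeros((4, 4))
        W[0, 1] = 5.0
        W[2, 3] = 7.0
        W[0, 2], W[0, 3], W[1, 2], W[1, 3] = 1.0, 2.0, 3.0, 4.0
        W = W + W.T
        pmap = sc.ParcelNetworkMap(np.array(["p0", "p1", "p2", "p3"]),
                                   np.array(["A", "A", "B", "B"]))
        out = sc.network_average(W, pmap)
        assert out.loc["A", "A"] == 5.0
        assert out.loc["B", "B"] == 7.0
        assert out.loc["A", "B"] == pytest.approx((1 + 2 + 3 + 4) / 4)
        assert out.loc["B", "A"] == out.loc["A", "B"]

    def test_constant_matrix(self):
        W = np.full((6, 6), 2.5)
        np.fill_diagonal(W, 0)
        pmap = sc.ParcelNetworkMap([f"p{i}" for i in range(6)],
                                   ["A"] * 3 + ["B"] * 3)
        out = sc.network_average(W, pmap)
        np.testing.assert_allclose(out.to_numpy(), 2.5)

    def test_parcel_permutation_invariance(self, rng):
        p = 12
        W = rng.standard_normal((p, p))
        W = W + W.T
        np.fill_diagonal(W, 0)
        nets = np.array(["A", "B", "C"])[rng.integers(0, 3, p)]
        pmap = sc.ParcelNetworkMap([f"p{i}" for i in range(p)], nets)
        out = sc.network_average(W, pmap)
        perm = rng.permutation(p)
        pmap2 = sc.ParcelNetworkMap([f"p{i}" for i in perm], nets[perm])
        out2 = sc.network_average(W[np.ix_(perm, perm)], pmap2)
        np.testing.assert_allclose(out.loc[out2.index, out2.columns].to_numpy(),
                                   out2.to_numpy(), atol=1e-12)

    def test_single_parcel_network_missing_marker(self):
        W = np.ones((3, 3)) - np.eye(3)
        pmap = sc.ParcelNetworkMap(["a", "b", "c"], ["A", "A", "B"])
        out = sc.network_average(W, pmap)
        assert np.isnan(out.loc["B", "B"])

    def test_commutes_with_subject_averaging(self, rng):
        p = 10
        nets = ["A"] * 4 + ["B"] * 3 + ["C"] * 3
        pmap = sc.ParcelNetworkMap([f"p{i}" for i in range(p)], nets)
        mats = []
        for _ in range(5):
            W = rng.standard_normal((p, p))
            W = W + W.T
            np.fill_diagonal(W, 0)
            mats.append(W)
        avg_then_net = sc.network_average(np.mean(mats, axis=0), pmap)
        net_then_avg = sum(sc.network_average(W, pmap) for W in mats) / 5
        np.testing.assert_allclose(avg_then_net.to_numpy(),
                                   net_then_avg.to_numpy(), atol=1e-12)


class TestNetworkwiseGLM:
    def test_planted_noiseless_pair_exact(self):
        cfg = sc.SynthConfig(n_subjects=20, n_parcels=12, n_networks=3,
                             noise_sd=0.0,
                             edge_effects=(("net1", "net2", 0.5),), seed=41)
        scores = np.linspace(-2, 2, 20)
        mats = sc.simulate_connectomes(cfg, scores)
        res = sc.networkwise_glm(mats, scores, cfg.network_map())
        tab = res.table.set_index(["network_a", "network_b"])
        assert tab.loc[("net1", "net2"), "beta"] == pytest.approx(0.5, abs=1e-12)
        others = tab.drop(index=("net1", "net2"))
        np.testing.assert_allclose(others["beta"], 0.0, atol=1e-12)

    def test_number_of_tests_for_18_networks(self, rng):
        p = 36
        nets = [f"N{i % 18}" for i in range(p)]
        pmap = sc.ParcelNetworkMap([f"p{i}" for i in range(p)], nets)
        mats = []
        for i in range(10):
            W = rng.standard_normal((p, p))
            W = W + W.T
            np.fill_diagonal(W, 0)
            mats.append(sc.ConnectivityMatrix(W, pmap.parcel_labels, f"s{i}"))
        res = sc.networkwise_glm(mats, rng.standard_normal(10), pmap)
        assert len(res.table) == 18 * 19 // 2 == 171

    def test_fdr_threshold_applied(self, rng):
        cfg = sc.SynthConfig(n_subjects=100, n_parcels=20, n_networks=4,
                             noise_sd=0.5,
                             edge_effects=(("net1", "net2", 1.0),), seed=43)
        scores = rng.standard_normal(100)
        mats = sc.simulate_connectomes(cfg, scores)
        res = sc.networkwise_glm(mats, scores, cfg.network_map())
        tab = res.table.set_index(["network_a", "network_b"])
        assert tab.loc[("net1", "net2"), "q"] < 0.05
        assert tab.loc[("net1", "net2"), "beta_thresholded"] != 0.0
        assert (res.table.loc[res.table["q"] >= 0.05, "beta_thresholded"] == 0).all()
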