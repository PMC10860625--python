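import numpy as np
import pytest
from scipy.spatial.distance import pdist

from chordrsa.patterns import (
    PatternGroundTruth,
    PatternSet,
    mds_embed,
    simulate_patterns,
)
from chordrsa.rdm import RDM, mean_rdm
from chordrsa.rsa import (
    UndefinedCorrelationError,
    control_template,
    crossnobis_rdm,
    estimate_noise_model,
    fisher_z,
    homotopy,
    select_pairs,
    typicality,
)

LABELS = ("145", "234", "134", "125", "235")


def make_set(patterns, residuals=None, labels=LABELS, **meta):
    if residuals is None:
        residuals = np.zeros((patterns.shape[0], 2, patterns.shape[2]))
    return PatternSet(patterns=patterns, residuals=residuals, condition_labels=labels, meta=meta)


def crossnobis_double_loop(B, P_norm=True):
    """Naive two-fold crossnobis oracle for M = 2 runs (identity noise)."""
    M, n_cond, P = B.shape
    assert M == 2
    out = []
    for i in range(n_cond):
        for j in range(i + 1, n_cond):
            acc, count = 0.0, 0
            for m in range(2):
                for n in range(2):
                    if m == n:
                        continue
                    d1 = B[m, i] - B[m, j]
                    d2 = B[n, i] - B[n, j]
                    acc += float(d1 @ d2)
                    count += 1
            out.append(acc / count / (P if P_norm else 1))
    return np.array(out)


class TestMdsEmbedding:
    def test_latent_distances_reproduce_target_exactly(self, euclidean_rdm):
        U = mds_embed(euclidean_rdm, n_voxels=64)
        got = pdist(U, metric="sqeuclidean") / 64
        np.testing.assert_allclose(got, euclidean_rdm.values, atol=1e-9)

    def test_non_euclidean_rdm_rejected(self):
        # strong violation of the triangle-ish embedding structure
        M = np.array(
            [
                [0, 10, 0.1, 0.1, 0.1],
                [10, 0, 0.1, 0.1, 0.1],
                [0.1, 0.1, 0, 0.1, 0.1],
                [0.1, 0.1, 0.1, 0, 0.1],
                [0.1, 0.1, 0.1, 0.1, 0],
            ],
            dtype=float,
        )
        with pytest.raises(ValueError):
            mds_embed(RDM.from_matrix(LABELS, M), n_voxels=32)


class TestSimulatePatterns:
    def test_noiseless_means_reproduce_target_geometry(self, euclidean_rdm):
        gt = PatternGroundTruth(
            true_rdm_contra=euclidean_rdm, noise_covariance=1e-14, n_voxels=80,
            n_runs=2, n_residual_samples=2,
        )
        pc, _ = simulate_patterns(gt, seed=0)
        d = pdist(pc.patterns[0], metric="sqeuclidean") / 80
        np.testing.assert_allclose(d, euclidean_rdm.values, atol=1e-5)

    def test_published_oracle_crossvalidated_mean_matches_target(self, euclidean_rdm):
        # identity noise, 2 runs: mean crossnobis over >= 1000 draws equals
        # the requested entry within Monte-Carlo error
        gt = PatternGroundTruth(
            true_rdm_contra=euclidean_rdm, noise_covariance=1.0, n_voxels=40,
            n_runs=2, n_residual_samples=2,
        )
        rng = np.random.default_rng(7)
        ests = np.empty((1000, 10))
        for r in range(1000):
            pc, _ = simulate_patterns(gt, seed=rng)
            ests[r] = crossnobis_rdm(pc).values
        se = ests.std(axis=0, ddof=1) / np.sqrt(len(ests))
        assert (np.abs(ests.mean(axis=0) - euclidean_rdm.values) < 4 * se).all()

    def test_identical_geometry_at_full_homotopy(self, euclidean_rdm):
        from scipy.stats import spearmanr

        gt = PatternGroundTruth(
            true_rdm_contra=euclidean_rdm, homotopy_level=1.0, noise_covariance=1e-14,
            n_voxels=60, n_runs=2, n_residual_samples=2,
        )
        pc, pi = simulate_patterns(gt, seed=1)
        dc = pdist(pc.patterns[0], metric="sqeuclidean")
        di = pdist(pi.patterns[0], metric="sqeuclidean")
        assert spearmanr(dc, di).statistic == pytest.approx(1.0)
        np.testing.assert_allclose(di, dc, rtol=1e-6)

    def test_zero_signal_gives_zero_mean_distance(self, euclidean_rdm):
        gt = PatternGroundTruth(
            true_rdm_contra=euclidean_rdm, signal_scale_by_hemisphere=(0.0, 0.0),
            noise_covariance=1.0, n_voxels=50, n_runs=3, n_residual_samples=2,
        )
        rng = np.random.default_rng(3)
        means = [crossnobis_rdm(simulate_patterns(gt, seed=rng)[0]).values.mean() for _ in range(400)]
        se = np.std(means, ddof=1) / np.sqrt(len(means))
        assert abs(np.mean(means)) < 3 * se

    def test_zero_homotopy_gives_zero_expected_cross_hemisphere_correlation(self, euclidean_rdm):
        # Monte-Carlo oracle: noiseless geometry, independent ipsi latents
        gt = PatternGroundTruth(
            true_rdm_contra=euclidean_rdm, homotopy_level=0.0, noise_covariance=1e-14,
            n_voxels=60, n_runs=2, n_residual_samples=2,
        )
        rng = np.random.default_rng(11)
        rs = []
        for _ in range(300):
            pc, pi = simulate_patterns(gt, seed=rng)
            rs.append(homotopy(crossnobis_rdm(pc), crossnobis_rdm(pi)).r)
        se = np.std(rs, ddof=1) / np.sqrt(len(rs))
        assert abs(np.mean(rs)) < 4 * se

    def test_non_positive_definite_covariance_rejected(self, euclidean_rdm):
        C = -np.eye(30)
        gt = PatternGroundTruth(true_rdm_contra=euclidean_rdm, noise_covariance=C, n_voxels=30)
        with pytest.raises(ValueError):
            simulate_patterns(gt, seed=0)


class TestNoiseModel:
    def test_white_residuals_approach_identity(self, rng):
        resid = rng.standard_normal((1, 4000, 20))
        nm = estimate_noise_model(resid)
        np.testing.assert_allclose(nm.covariance, np.eye(20), atol=0.12)
        off = nm.covariance[~np.eye(20, dtype=bool)]
        assert np.abs(off).max() < 0.12

    def test_full_shrinkage_is_exactly_diagonal(self, rng):
        resid = rng.standard_normal((2, 50, 10))
        nm = estimate_noise_model(resid, shrinkage=1.0)
        off = nm.covariance[~np.eye(10, dtype=bool)]
        assert np.abs(off).max() == 0.0

    def test_ar_correlated_residuals_match_direct_covariance_oracle(self, rng):
        # spatially AR(1)-correlated voxels; zero shrinkage = raw pooled cov
        P, n = 12, 400
        C = 0.7 ** np.abs(np.subtract.outer(np.arange(P), np.arange(P)))
        L = np.linalg.cholesky(C)
        resid = rng.standard_normal((2, n, P)) @ L.T
        nm = estimate_noise_model(resid, shrinkage=0.0)
        X = np.concatenate([r - r.mean(0) for r in resid])
        direct = X.T @ X / (X.shape[0] - 1)
        np.testing.assert_allclose(nm.covariance, direct, atol=1e-10)

    def test_whitening_makes_residual_covariance_identity(self, rng):
        P = 10
        C = 0.6 ** np.abs(np.subtract.outer(np.arange(P), np.arange(P)))
        L = np.linalg.cholesky(C)
        resid = rng.standard_normal((1, 20000, P)) @ L.T
        nm = estimate_noise_model(resid, shrinkage=0.0)
        white = resid[0] @ nm.whitener
        S = np.cov(white.T)
        np.testing.assert_allclose(S, np.eye(P), atol=0.08)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            estimate_noise_model(np.zeros((1, 1, 5)))


class TestCrossnobis:
    def test_identical_patterns_noise_free_distance_is_scaled_squared_norm(self, rng):
        P = 16
        base = rng.standard_normal((5, P))
        B = np.stack([base, base, base])  # identical across 3 runs
        rdm = crossnobis_rdm(make_set(B))
        expected = pdist(base, metric="sqeuclidean") / P
        np.testing.assert_allclose(rdm.values, expected, atol=1e-12)

    def test_duplicated_condition_distance_zero(self, rng):
        P = 8
        base = rng.standard_normal((5, P))
        base[1] = base[0]
        B = np.stack([base, base])
        rdm = crossnobis_rdm(make_set(B))
        assert rdm.entry("145", "234") == pytest.approx(0.0, abs=1e-12)

    def test_equals_double_loop_oracle_on_small_instances(self, rng):
        for P in (2, 3, 5):
            B = rng.standard_normal((2, 5, P))
            rdm = crossnobis_rdm(make_set(B))
            np.testing.assert_allclose(rdm.values, crossnobis_double_loop(B), atol=1e-10)

    def test_symmetry_by_construction(self, rng):
        B = rng.standard_normal((3, 5, 10))
        M = crossnobis_rdm(make_set(B)).as_matrix()
        np.testing.assert_array_equal(M, M.T)

    def test_scaling_pattern_differences_increases_every_distance(self, euclidean_rdm):
        gt1 = PatternGroundTruth(true_rdm_contra=euclidean_rdm, noise_covariance=1e-14,
                                 n_voxels=40, n_runs=2, n_residual_samples=2)
        big = RDM(euclidean_rdm.labels, euclidean_rdm.values * 4.0)  # lambda = 2 on patterns
        gt2 = PatternGroundTruth(true_rdm_contra=big, noise_covariance=1e-14,
                                 n_voxels=40, n_runs=2, n_residual_samples=2)
        d1 = crossnobis_rdm(simulate_patterns(gt1, seed=0)[0]).values
        d2 = crossnobis_rdm(simulate_patterns(gt2, seed=0)[0]).values
        assert (d2 > d1).all()

    def test_mismatched_voxel_count_with_noise_model_rejected(self, rng):
        B = rng.standard_normal((2, 5, 10))
        nm = estimate_noise_model(rng.standard_normal((1, 50, 8)))
        with pytest.raises(ValueError):
            crossnobis_rdm(make_set(B), nm)


class TestSelectPairs:
    def test_all_entries_mean_of_constant_rdm(self):
        rdm = RDM(LABELS, np.full(10, 3.3))
        entries, mean = select_pairs(rdm, "all")
        assert len(entries) == 10
        assert mean == pytest.approx(3.3)

    def test_named_pairs_mean_by_hand_indexing(self, euclidean_rdm):
        # easiest pair (234-145) and most difficult pair (235-125)
        entries, mean = select_pairs(euclidean_rdm, [("234", "145"), ("235", "125")])
        hand = (euclidean_rdm.entry("145", "234") + euclidean_rdm.entry("125", "235")) / 2
        assert mean == pytest.approx(hand)
        assert len(entries) == 2

    def test_unknown_pair_label_rejected(self, euclidean_rdm):
        with pytest.raises(KeyError):
            select_pairs(euclidean_rdm, [("145", "999")])

    def test_five_conditions_enumerate_ten_pairs(self, euclidean_rdm):
        assert len(euclidean_rdm.pairs()) == 10


class TestComparisons:
    def test_scaled_copy_has_unit_correlation(self, euclidean_rdm):
        double = RDM(euclidean_rdm.labels, 2 * euclidean_rdm.values)
        assert homotopy(euclidean_rdm, double, method="spearman").r == pytest.approx(1.0)
        assert homotopy(euclidean_rdm, double, method="pearson").r == pytest.approx(1.0)

    def test_anti_ordered_rdms_give_minus_one(self, euclidean_rdm):
        neg = RDM(euclidean_rdm.labels, -euclidean_rdm.values)
        assert homotopy(euclidean_rdm, neg).r == pytest.approx(-1.0)

    def test_independent_random_rdms_average_zero(self, rng):
        rs = []
        for _ in range(1000):
            a = RDM(LABELS, rng.standard_normal(10))
            b = RDM(LABELS, rng.standard_normal(10))
            rs.append(homotopy(a, b).r)
        se = np.std(rs, ddof=1) / np.sqrt(len(rs))
        assert abs(np.mean(rs)) < 3 * se

    def test_zero_variance_rdm_signals_undefined_correlation(self, euclidean_rdm):
        flat = RDM(LABELS, np.ones(10))
        with pytest.raises(UndefinedCorrelationError):
            homotopy(euclidean_rdm, flat)

    def test_fisher_z_is_atanh_and_finite_at_unit_r(self):
        assert fisher_z(0.5) == pytest.approx(np.arctanh(0.5))
        assert np.isfinite(fisher_z(1.0)) and np.isfinite(fisher_z(-1.0))

    def test_typicality_of_template_itself_is_one(self, euclidean_rdm):
        assert typicality(euclidean_rdm, euclidean_rdm).r == pytest.approx(1.0)

    def test_template_of_identical_controls_is_any_one_of_them(self, euclidean_rdm):
        tpl = control_template([euclidean_rdm, euclidean_rdm, euclidean_rdm])
        np.testing.assert_allclose(tpl.values, euclidean_rdm.values)

    def test_template_exclusion_and_empty_set(self, euclidean_rdm, rng):
        other = RDM(LABELS, rng.standard_normal(10))
        tpl = control_template([euclidean_rdm, other], exclude=1)
        np.testing.assert_allclose(tpl.values, euclidean_rdm.values)
        with pytest.raises(ValueError):
            control_template([euclidean_rdm], exclude=0)

    def test_graded_template_similarity_orders_recovered_typicality(self, euclidean_rdm, rng):
        # subjects constructed with increasing mixture weight toward the template
        noise = rng.standard_normal(10)
        rs = []
        for w in (0.2, 0.5, 0.9):
            subj = RDM(LABELS, w * euclidean_rdm.values + (1 - w) * noise)
            rs.append(typicality(subj, euclidean_rdm).r)
        assert rs[0] < rs[1] < rs[2]


class TestSerialization:
    def test_pattern_set_round_trips_through_csv_directory(self, tmp_path, rng):
        from chordrsa.patterns import load_pattern_set, save_pattern_set

        ps = make_set(rng.standard_normal((3, 5, 7)), rng.standard_normal((3, 11, 7)),
                      hemisphere="contra")
        save_pattern_set(ps, tmp_path / "ps")
        back = load_pattern_set(tmp_path / "ps")
        np.testing.assert_allclose(back.patterns, ps.patterns)
        np.testing.assert_allclose(back.residuals, ps.residuals)
        assert back.condition_labels == ps.condition_labels
        assert back.meta["hemisphere"] == "contra"

    def test_rdm_round_trips_through_long_frame(self, euclidean_rdm):
        back = RDM.from_long_frame(euclidean_rdm.to_long_frame())
        assert back.labels == euclidean_rdm.labels
        np.testing.assert_allclose(back.values, euclidean_rdm.values)


class TestMeanRdm:
    def test_entrywise_mean_and_label_check(self, euclidean_rdm, rng):
        other = RDM(LABELS, rng.standard_normal(10))
        m = mean_rdm([euclidean_rdm, other])
        np.testing.assert_allclose(m.values, (euclidean_rdm.values + other.values) / 2)
        with pytest.raises(ValueError):
            mean_rdm([euclidean_rdm, RDM(("a", "b", "c", "d", "e"), other.values)])
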