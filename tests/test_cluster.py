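"""Consensus machinery: matrices, PAC, null references, k selection."""

import numpy as np
import pandas as pd
import pytest
from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_rand_score

import gliosplice as gs
from gliosplice.cluster import kmeans_labels


def two_clouds(n_per=30, sep=20.0, seed=0, f=4):
    rng = np.random.default_rng(seed)
    a = rng.normal(0, 1, (n_per, f))
    b = rng.normal(sep, 1, (n_per, f))
    return np.vstack([a, b])


class TestConsensusMatrix:
    def test_separable_limit_is_binary(self):
        X = two_clouds()
        M = gs.consensus_matrix(X, k=2, seed=1)
        off = M[~np.eye(len(M), dtype=bool)]
        assert set(np.round(off, 12)) <= {0.0, 1.0}
        assert (np.diag(M) == 1.0).all()

    def test_determinism(self):
        X = two_clouds(seed=3)
        M1 = gs.consensus_matrix(X, k=2, seed=9)
        M2 = gs.consensus_matrix(X, k=2, seed=9)
        assert np.array_equal(M1, M2)

    def test_single_cloud_is_ambiguous(self):
        rng = np.random.default_rng(2)
        X = rng.normal(0, 1, (60, 5))
        M = gs.consensus_matrix(X, k=2, seed=4)
        _, pac = gs.cdf_and_pac(M)
        assert pac > 0.3

    def test_permutation_equivariance_on_separable_data(self):
        X = two_clouds(seed=5)
        perm = np.random.default_rng(0).permutation(len(X))
        M = gs.consensus_matrix(X, k=2, seed=6)
        Mp = gs.consensus_matrix(X[perm], k=2, seed=7)
        # binary in the separable limit, so equivariance holds exactly
        assert np.array_equal(M[np.ix_(perm, perm)], Mp)

    def test_pam_inner_agrees_on_separable_data(self):
        X = two_clouds(seed=8)
        M = gs.consensus_matrix(X, k=2, seed=1, inner="pam")
        off = M[~np.eye(len(M), dtype=bool)]
        assert set(np.round(off, 12)) <= {0.0, 1.0}

    def test_k_bounds(self):
        with pytest.raises(ValueError):
            gs.consensus_matrix(two_clouds(), k=1)

    def test_inner_kmeans_matches_sklearn_on_separable_data(self):
        X = two_clouds(n_per=40, seed=11)
        ours = kmeans_labels(X[None], 2, np.random.default_rng(0))[0]
        ref = KMeans(n_clusters=2, n_init=3, random_state=0).fit_predict(X)
        assert adjusted_rand_score(ours, ref) == 1.0


class TestPac:
    def test_binary_matrix_pac_zero(self):
        M = np.kron(np.eye(2), np.ones((4, 4)))
        _, pac = gs.cdf_and_pac(M)
        assert pac == 0.0

    def test_all_half_pac_one(self):
        M = np.full((6, 6), 0.5)
        np.fill_diagonal(M, 1.0)
        _, pac = gs.cdf_and_pac(M)
        assert pac == 1.0

    def test_direct_count_oracle(self):
        # upper triangle holds each of (0, 0.05, 0.5, 0.95, 1.0) twice:
        # exactly 2/10 entries lie in the ambiguous window (0.1, 0.9]
        vals = [0.0, 0.05, 0.5, 0.95, 1.0] * 2
        M = np.eye(5)
        M[np.triu_indices(5, k=1)] = vals
        M = M + M.T - np.diag(np.diag(M))
        np.fill_diagonal(M, 1.0)
        _, pac = gs.cdf_and_pac(M)
        assert pac == pytest.approx(1 / 5)

    def test_cdf_is_monotone(self):
        rng = np.random.default_rng(0)
        M = rng.random((10, 10))
        cdf, _ = gs.cdf_and_pac((M + M.T) / 2)
        assert (np.diff(cdf["cdf"]) >= 0).all()


class TestNullReferences:
    def test_isotropic_limit(self):
        rng = np.random.default_rng(0)
        X = rng.normal(0, 1, (500, 2))
        nulls = gs.simulate_null_references(X, n_null=5, seed=1)
        for N in nulls:
            C = np.cov(N.T)
            assert abs(C[0, 1]) < 0.15
            assert abs(C[0, 0] - 1.0) < 0.2

    def test_correlation_structure_preserved(self):
        rng = np.random.default_rng(1)
        z = rng.normal(0, 1, (400, 3))
        X = np.c_[z[:, 0], 0.9 * z[:, 0] + 0.4 * z[:, 1], z[:, 2]]
        target = np.corrcoef(X.T)
        rms = []
        for N in gs.simulate_null_references(X, n_null=10, seed=2):
            rms.append(np.sqrt(((np.corrcoef(N.T) - target) ** 2).mean()))
        assert np.mean(rms) < 0.1

    def test_determinism_and_zero_variance_warning(self):
        X = np.random.default_rng(3).normal(0, 1, (50, 3))
        a = gs.simulate_null_references(X, n_null=2, seed=5)
        b = gs.simulate_null_references(X, n_null=2, seed=5)
        assert all(np.array_equal(x, y) for x, y in zip(a, b))
        Xz = np.c_[X, np.zeros(50)]
        with pytest.warns(UserWarning, match="zero-variance"):
            gs.simulate_null_references(Xz, n_null=1, seed=0)


class TestRcsi:
    def test_identity_case(self):
        rcsi, _ = gs.rcsi_and_pvalue(0.3, [0.3, 0.3, 0.3])
        assert rcsi == pytest.approx(0.0)

    def test_extreme_case(self):
        _, p = gs.rcsi_and_pvalue(0.01, [0.5, 0.4, 0.3, 0.2])
        assert p == pytest.approx(1 / 5)

    def test_direct_formula(self):
        rcsi, p = gs.rcsi_and_pvalue(0.1, [0.4, 0.2, 0.05])
        assert rcsi == pytest.approx(np.log((0.65 / 3) / 0.1))
        assert p == pytest.approx(2 / 4)

    def test_zero_real_pac_sentinel(self):
        rcsi, p = gs.rcsi_and_pvalue(0.0, [0.4, 0.2])
        assert np.isinf(rcsi) and 0 < p <= 1


class TestSelectK:
    def test_max_rcsi_among_significant(self):
        stats = pd.DataFrame({
            "rcsi": [0.5, 1.2, 0.9],
            "empirical_p": [0.01, 0.02, 0.20],
        }, index=[2, 3, 4])
        assert gs.select_k(stats) == 3

    def test_no_structure_verdict(self):
        stats = pd.DataFrame({"rcsi": [1.0], "empirical_p": [0.3]}, index=[2])
        assert gs.select_k(stats) is None


class TestAssignClusters:
    def test_block_diagonal_exact(self):
        sizes = [5, 3, 2]
        M = np.zeros((10, 10))
        start = 0
        for s in sizes:
            M[start:start + s, start:start + s] = 1.0
            start += s
        labels = gs.assign_clusters(M, 3)
        assert labels.tolist() == [1] * 5 + [2] * 3 + [3] * 2

    def test_largest_cluster_is_one(self):
        M = np.zeros((7, 7))
        M[:2, :2] = 1.0
        M[2:, 2:] = 1.0
        labels = gs.assign_clusters(M, 2)
        assert (labels[2:] == 1).all() and (labels[:2] == 2).all()


def test_pac_nondecreasing_with_noise():
    """Degrading separation cannot make clustering look more stable."""
    pacs = []
    for conc in (400.0, 25.0, 4.0):   # tight -> noisy PSI
        cfg = gs.SimulationConfig(
            n_samples=90, n_events=40, k_true=3, fraction_informative=0.4,
            mean_gap=0.35, concentration=conc, n_prognostic_events=0,
            missing_event_frac=0.0, seed=13)
        psi, _, _, truth = gs.simulate_cohort(cfg)
        X = gs.prepare_features(psi, truth.informative_events)
        M = gs.consensus_matrix(X, k=3, seed=17)
        pacs.append(gs.cdf_and_pac(M)[1])
    assert pacs[0] <= pacs[1] + 1e-9 <= pacs[2] + 2e-9


def complete_informative(psi, truth):
    """Informative events without missing PSI (the screen's no-missing rule)."""
    return list(psi.data.loc[truth.informative_events].dropna().index)


def test_run_consensus_recovers_planted_k(strong_cohort):
    psi, _, _, truth = strong_cohort
    X = gs.prepare_features(psi, complete_informative(psi, truth))
    res = gs.run_consensus(X, seed=23)
    assert res.chosen_k == 3
    assert adjusted_rand_score(truth.labels, res.labels) >= 0.9
    tab = res.per_k_table()
    assert set(tab.index) == set(range(2, 9))
    assert ((tab["empirical_p"] > 0) & (tab["empirical_p"] <= 1)).all()


def test_prepare_features_standardizes(strong_cohort):
    psi, _, _, truth = strong_cohort
    events = complete_informative(psi, truth)
    X = gs.prepare_features(psi, events)
    assert X.shape == (psi.n_samples, len(events))
    assert np.allclose(X.mean(axis=0), 0, atol=1e-9)
    with pytest.raises(ValueError, match="missing"):
        gs.prepare_features(psi, psi.event_ids)
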