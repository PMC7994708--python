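import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import symptomnet as sn
from symptomnet.ggm import ebic_score, glasso_precision, precision_to_pcor
from conftest import nodewise_pcor_oracle, random_pd_correlation


def equicorrelation(p, r):
    C = np.full((p, p), r)
    np.fill_diagonal(C, 1.0)
    return sn.CorrelationMatrix(C, "pearson", 500)


class TestPrecisionToPcor:
    def test_identity_gives_empty(self):
        np.testing.assert_array_equal(precision_to_pcor(np.eye(4)), np.zeros((4, 4)))

    def test_two_by_two_formula(self):
        K = np.array([[1.0, -0.5], [-0.5, 1.0]])
        assert precision_to_pcor(K)[0, 1] == pytest.approx(0.5)

    def test_equicorrelation_triple_matches_recursion_oracle(self):
        # pcor_12.3 = (r12 - r13 r23) / sqrt((1-r13^2)(1-r23^2)) with all r=0.5
        r = 0.5
        expected = (r - r * r) / (1 - r * r)
        K = np.linalg.inv(equicorrelation(3, r).values)
        W = precision_to_pcor(K)
        iu = np.triu_indices(3, 1)
        np.testing.assert_allclose(W[iu], expected, atol=1e-12)
        assert expected == pytest.approx(1 / 3)

    def test_non_pd_rejected(self):
        with pytest.raises(np.linalg.LinAlgError):
            precision_to_pcor(np.array([[1.0, 2.0], [2.0, 1.0]]))


class TestEstimateGGM:
    def test_identity_gives_empty_network(self):
        net = sn.estimate_ggm(sn.CorrelationMatrix(np.eye(5), "pearson", 100))
        assert sn.global_strength(net) == 0.0
        np.testing.assert_array_equal(net.weights, np.zeros((5, 5)))

    def test_equicorrelation_edges_one_third(self):
        net = sn.estimate_ggm(equicorrelation(3, 0.5))
        iu = np.triu_indices(3, 1)
        np.testing.assert_allclose(net.weights[iu], 1 / 3, atol=1e-12)

    def test_matches_nodewise_regression_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(25):
            C = random_pd_correlation(8, rng)
            net = sn.estimate_ggm(sn.CorrelationMatrix(C, "pearson", 100))
            W_oracle, _ = nodewise_pcor_oracle(C)
            np.testing.assert_allclose(net.weights, W_oracle, atol=1e-8)

    def test_node_relabeling_equivariance(self):
        rng = np.random.default_rng(2)
        C = random_pd_correlation(6, rng)
        perm = rng.permutation(6)
        net = sn.estimate_ggm(sn.CorrelationMatrix(C, "pearson", 50))
        net_p = sn.estimate_ggm(sn.CorrelationMatrix(C[np.ix_(perm, perm)], "pearson", 50))
        np.testing.assert_allclose(net_p.weights, net.weights[np.ix_(perm, perm)], atol=1e-10)


class TestPredictability:
    def test_identity_gives_zero(self):
        pv = sn.node_predictability(sn.CorrelationMatrix(np.eye(4), "pearson", 50))
        np.testing.assert_array_equal(pv.r2, np.zeros(4))

    def test_bivariate_r2_is_r_squared(self):
        pv = sn.node_predictability(equicorrelation(2, 0.6))
        np.testing.assert_allclose(pv.r2, 0.36, atol=1e-12)

    def test_equicorrelation_triple_r2_one_third(self):
        # oracle: R^2_j = r' R^{-1} r with r = (0.5, 0.5), R = [[1,.5],[.5,1]]
        r = np.array([0.5, 0.5])
        R = np.array([[1.0, 0.5], [0.5, 1.0]])
        expected = r @ np.linalg.solve(R, r)
        pv = sn.node_predictability(equicorrelation(3, 0.5))
        np.testing.assert_allclose(pv.r2, expected, atol=1e-12)
        assert expected == pytest.approx(1 / 3)

    def test_matches_ols_r2_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(25):
            C = random_pd_correlation(7, rng)
            pv = sn.node_predictability(sn.CorrelationMatrix(C, "pearson", 100))
            _, r2_oracle = nodewise_pcor_oracle(C)
            np.testing.assert_allclose(pv.r2, r2_oracle, atol=1e-8)


class TestDescriptives:
    def test_global_strength_arithmetic(self):
        W = np.zeros((3, 3))
        W[0, 1] = W[1, 0] = 0.3
        W[0, 2] = W[2, 0] = -0.2
        net = sn.NetworkModel(W, ("a", "b", "c"), "nonregularized", "pearson", 10)
        assert sn.global_strength(net) == pytest.approx(0.5)

    def test_single_edge_strength_centrality(self):
        W = np.zeros((4, 4))
        W[0, 1] = W[1, 0] = 0.4
        net = sn.NetworkModel(W, tuple("abcd"), "nonregularized", "pearson", 10)
        s = sn.strength_centrality(net)
        assert s["a"] == s["b"] == pytest.approx(0.4)
        assert s["c"] == s["d"] == 0.0

    @settings(max_examples=25, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_handshake_identity(self, seed):
        rng = np.random.default_rng(seed)
        W = rng.uniform(-0.5, 0.5, size=(6, 6))
        W = (W + W.T) / 2
        np.fill_diagonal(W, 0.0)
        net = sn.NetworkModel(W, tuple(range(6)), "nonregularized", "pearson", 10)
        assert sn.strength_centrality(net).sum() == pytest.approx(2 * sn.global_strength(net))

    def test_display_filter(self):
        W = np.zeros((3, 3))
        W[0, 1] = W[1, 0] = 0.05
        W[0, 2] = W[2, 0] = 0.15
        W[1, 2] = W[2, 1] = -0.2
        net = sn.NetworkModel(W, ("a", "b", "c"), "nonregularized", "pearson", 10)
        assert len(sn.display_filter(net, 0.1)) == 2
        assert len(sn.display_filter(net, 0.0)) == 3
        # the model itself is untouched
        assert net.weights[0, 1] == pytest.approx(0.05)

    def test_fisher_z_edge_test_shape(self, study_panel):
        X = sn.wave_matrix(study_panel, "t0")
        net = sn.GaussianGraphicalModel().fit(X).to_network()
        table = sn.fisher_z_edge_test(net)
        assert len(table) == 55
        assert set(table.columns) == {"node_a", "node_b", "weight", "p", "retained"}


@pytest.fixture(scope="module")
def sparse_sample():
    rng = np.random.default_rng(7)
    P = sn.ring_pcor(11)
    K = -P.copy()
    np.fill_diagonal(K, 1.0)
    S = np.linalg.inv(K)
    d = np.sqrt(np.diag(S))
    X = rng.multivariate_normal(np.zeros(11), S / np.outer(d, d), size=800)
    return sn.pearson_matrix(X), P


class TestEBICGlasso:
    def test_full_shrinkage_gives_empty_network(self, sparse_sample):
        C, _ = sparse_sample
        lam_max = np.max(np.abs(C.values - np.eye(C.p)))
        K = glasso_precision(C.values, lam_max * 1.001)
        W = precision_to_pcor(K)
        np.testing.assert_allclose(W, 0.0, atol=1e-10)

    def test_vanishing_penalty_matches_unregularized(self, sparse_sample):
        C, _ = sparse_sample
        W_glasso = precision_to_pcor(glasso_precision(C.values, 1e-7))
        W_unreg = sn.estimate_ggm(C).weights
        np.testing.assert_allclose(W_glasso, W_unreg, atol=1e-4)

    def test_edge_count_shrinks_with_penalty(self, sparse_sample):
        C, _ = sparse_sample
        lam_max = np.max(np.abs(C.values - np.eye(C.p)))
        counts = []
        for lam in np.geomspace(0.01, lam_max, 8):
            K = glasso_precision(C.values, lam)
            iu = np.triu_indices(C.p, 1)
            counts.append(int(np.count_nonzero(np.abs(K[iu]) > 1e-10)))
        assert counts == sorted(counts, reverse=True)

    def test_selected_model_recovers_support(self, sparse_sample):
        C, P = sparse_sample
        net = sn.ebic_glasso(C)
        assert net.method == "ebic_glasso"
        assert net.lambda_selected is not None
        iu = np.triu_indices(11, 1)
        truth = P[iu] != 0
        found = net.weights[iu] != 0
        tp = np.sum(truth & found)
        f1 = 2 * tp / (2 * tp + np.sum(~truth & found) + np.sum(truth & ~found))
        assert f1 >= 0.8  # n=800 here; the large-n check lives in the acceptance suite

    def test_ebic_score_penalizes_extra_edges(self):
        C = equicorrelation(4, 0.0)
        K_dense = np.eye(4) * 1.05
        K_dense[0, 1] = K_dense[1, 0] = 0.04
        assert ebic_score(np.eye(4), C.values, 100, 0.5) < ebic_score(K_dense, C.values, 100, 0.5)
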