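"""Spearman / CLR / PCLRC inference behaviour and invariants."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays
from scipy.stats import spearmanr

from covnet.network import (
    PclrcConfig,
    build_network,
    clr_scores,
    filter_network,
    pclrc_probabilities,
    spearman_matrix,
)


class TestSpearman:
    def test_monotone_transform_gives_perfect_correlation(self):
        x = np.linspace(0.1, 3.0, 25)
        data = np.column_stack([x, np.exp(x)])
        assert spearman_matrix(data)[0, 1] == pytest.approx(1.0)

    def test_hand_computed_rank_correlation(self):
        data = np.array([[1.0, 3.0], [2.0, 1.0], [3.0, 2.0]])
        assert spearman_matrix(data)[0, 1] == pytest.approx(-0.5)

    def test_duplicated_column_gives_unit_entry(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=30)
        data = np.column_stack([x, x, rng.normal(size=30)])
        assert spearman_matrix(data)[0, 1] == pytest.approx(1.0)

    def test_matches_scipy_on_tied_data(self):
        rng = np.random.default_rng(1)
        data = rng.integers(0, 5, size=(40, 6)).astype(float)  # plenty of ties
        expected = spearmanr(data).statistic
        np.testing.assert_allclose(spearman_matrix(data), expected, atol=1e-12)

    def test_constant_column_zeroed_with_warning(self):
        data = np.column_stack([np.ones(20), np.arange(20.0), np.arange(20.0) ** 2])
        with pytest.warns(UserWarning, match="constant"):
            R = spearman_matrix(data)
        assert np.all(R[0, 1:] == 0) and np.all(R[1:, 0] == 0)
        assert R[1, 2] == pytest.approx(1.0)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            spearman_matrix(np.ones((2, 3)))


class TestClr:
    def test_flat_background_gives_zero_scores(self):
        R = np.full((5, 5), 0.4)
        np.fill_diagonal(R, 1.0)
        assert np.all(clr_scores(R) == 0.0)

    def test_outstanding_edge_has_largest_score(self):
        R = np.full((4, 4), 0.2)
        np.fill_diagonal(R, 1.0)
        R[0, 1] = R[1, 0] = 0.9
        z = clr_scores(R)
        expected = _brute_force_clr(R)
        np.testing.assert_allclose(z, expected, atol=1e-12)
        iu = np.triu_indices(4, 1)
        assert np.argmax(z[iu]) == 0  # edge (0, 1)

    def test_relabeling_permutes_scores(self):
        rng = np.random.default_rng(2)
        R = rng.uniform(-1, 1, (6, 6))
        R = (R + R.T) / 2
        np.fill_diagonal(R, 1.0)
        perm = rng.permutation(6)
        z = clr_scores(R)
        z_perm = clr_scores(R[np.ix_(perm, perm)])
        np.testing.assert_allclose(z_perm, z[np.ix_(perm, perm)], atol=1e-12)

    def test_asymmetric_input_rejected(self):
        with pytest.raises(ValueError):
            clr_scores(np.arange(9.0).reshape(3, 3))


def _brute_force_clr(R: np.ndarray) -> np.ndarray:
    """Literal per-edge loop used as an independent oracle."""
    p = R.shape[0]
    s = np.abs(R)
    out = np.zeros((p, p))
    for i in range(p):
        for j in range(p):
            if i == j:
                continue
            bg_i = [s[i, t] for t in range(p) if t != i]
            bg_j = [s[j, t] for t in range(p) if t != j]
            zi = max(0.0, (s[i, j] - np.mean(bg_i)) / np.std(bg_i)) if np.std(bg_i) else 0.0
            zj = max(0.0, (s[i, j] - np.mean(bg_j)) / np.std(bg_j)) if np.std(bg_j) else 0.0
            out[i, j] = np.sqrt(zi**2 + zj**2)
    return out


class TestPclrc:
    def test_duplicated_features_get_probability_one(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((200, 20))
        X[:, 1] = X[:, 0]
        P = pclrc_probabilities(X, PclrcConfig(n_iterations=100, seed=4))
        assert P[0, 1] >= 0.99

    def test_null_data_probabilities_track_keep_fraction(self):
        rng = np.random.default_rng(5)
        X = rng.standard_normal((150, 15))
        cfg = PclrcConfig(n_iterations=200, keep_fraction=0.30, seed=6)
        P = pclrc_probabilities(X, cfg)
        iu = np.triu_indices(15, 1)
        assert abs(P[iu].mean() - 0.30) < 0.05
        assert (P[iu] >= 0.90).mean() < 0.10

    def test_single_iteration_probabilities_are_binary(self):
        rng = np.random.default_rng(7)
        X = rng.standard_normal((40, 8))
        P = pclrc_probabilities(X, PclrcConfig(n_iterations=1, seed=8))
        assert set(np.unique(P)) <= {0.0, 1.0}

    def test_probabilities_are_empirical_frequencies(self):
        rng = np.random.default_rng(9)
        X = rng.standard_normal((60, 6))
        cfg = PclrcConfig(n_iterations=17, seed=10)
        P = pclrc_probabilities(X, cfg)
        counts = P * 17
        np.testing.assert_allclose(counts, np.round(counts), atol=1e-9)

    def test_seeded_determinism(self):
        rng = np.random.default_rng(11)
        X = rng.standard_normal((80, 8))
        cfg = PclrcConfig(n_iterations=50, seed=12)
        np.testing.assert_array_equal(
            pclrc_probabilities(X, cfg), pclrc_probabilities(X, cfg)
        )


class TestFilter:
    def test_threshold_branches(self):
        R = np.array([[1.0, 0.7, 0.99], [0.7, 1.0, -0.5], [0.99, -0.5, 1.0]])
        P = np.array([[0.0, 0.95, 0.89], [0.95, 0.0, 0.90], [0.89, 0.90, 0.0]])
        A = filter_network(R, P, 0.90)
        assert A[0, 1] == pytest.approx(0.7)  # p >= threshold keeps r
        assert A[0, 2] == 0.0  # p just below drops
        assert A[1, 2] == pytest.approx(-0.5)  # boundary p == 0.90 retained
        assert np.all(np.diag(A) == 0)

    def test_raising_threshold_never_adds_edges(self):
        rng = np.random.default_rng(13)
        R = rng.uniform(-1, 1, (10, 10))
        R = (R + R.T) / 2
        P = rng.uniform(0, 1, (10, 10))
        P = (P + P.T) / 2
        low = filter_network(R, P, 0.5) != 0
        high = filter_network(R, P, 0.8) != 0
        assert np.all(high <= low)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            filter_network(np.eye(3), np.eye(4))


class TestBuildNetwork:
    def test_planted_block_edges_recovered(self):
        rng = np.random.default_rng(14)
        p, n, rho = 12, 250, 0.9
        cov = np.eye(p)
        cov[:4, :4] = rho
        np.fill_diagonal(cov, 1.0)
        X = rng.multivariate_normal(np.zeros(p), cov, size=n)
        net = build_network(X, PclrcConfig(n_iterations=200, seed=15))
        block_edges = [(i, j) for i in range(4) for j in range(i + 1, 4)]
        for i, j in block_edges:
            assert net.adjacency[i, j] > 0.5
        iu = np.triu_indices(p, 1)
        null = [net.adjacency[i, j] != 0 for i, j in zip(*iu) if j >= 4]
        assert np.mean(null) < 0.05

    def test_network_invariants(self):
        rng = np.random.default_rng(16)
        X = rng.standard_normal((60, 8))
        net = build_network(X, PclrcConfig(n_iterations=30, seed=17))
        assert np.allclose(net.adjacency, net.adjacency.T)
        assert np.all(np.diag(net.adjacency) == 0)
        assert np.all((net.probabilities >= 0) & (net.probabilities <= 1))
        assert np.all(np.abs(net.adjacency) <= 1)
        nz = net.adjacency != 0
        assert np.all(net.probabilities[nz] >= net.settings["probability_threshold"])

    def test_no_resampling_is_invariant_to_sample_order(self):
        rng = np.random.default_rng(18)
        X = rng.standard_normal((50, 6))
        cfg = PclrcConfig(n_iterations=1, subsample_fraction=1.0, seed=0)
        a1 = build_network(X, cfg).adjacency
        a2 = build_network(X[rng.permutation(50)], cfg).adjacency
        np.testing.assert_allclose(a1, a2, atol=1e-12)

    def test_export_round_trip_and_display_threshold(self, tmp_path):
        rng = np.random.default_rng(19)
        X = rng.standard_normal((80, 6))
        X[:, 1] = X[:, 0] + 0.1 * rng.standard_normal(80)
        net = build_network(X, PclrcConfig(n_iterations=50, seed=20))
        edges = net.edge_list()
        strong = net.edge_list(min_abs_weight=0.6)
        assert set(strong["weight"]).issubset(set(edges["weight"]))
        assert np.all(np.abs(strong["weight"]) >= 0.6)
        gpath = tmp_path / "net.graphml"
        net.to_graphml(gpath)
        import networkx as nx

        g = nx.read_graphml(gpath)
        assert g.number_of_nodes() == 6
        assert g.number_of_edges() == len(edges)


@given(
    arrays(
        np.float64,
        (5, 5),
        elements=st.floats(-1, 1, allow_nan=False),
    )
)
def test_clr_scores_nonnegative_and_symmetric(mat):
    R = (mat + mat.T) / 2
    np.fill_diagonal(R, 1.0)
    z = clr_scores(R)
    assert np.all(z >= 0)
    np.testing.assert_allclose(z, z.T, atol=1e-10)
    assert np.all(np.diag(z) == 0)
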