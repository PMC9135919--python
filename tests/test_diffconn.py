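"""Connectivity, differential connectivity, permutation P-values and BH."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from covnet.diffconn import (
    _permutation_pvalues,
    bh_adjust,
    connectivity,
    differential_connectivity,
    pairwise_significance_frequency,
    permutation_test,
)
from covnet.network import InferredNetwork, PclrcConfig


def _net(adj: np.ndarray) -> InferredNetwork:
    p = adj.shape[0]
    return InferredNetwork(
        correlations=adj,
        probabilities=np.ones((p, p)),
        adjacency=adj,
        features=[f"feat_{i:03d}" for i in range(p)],
    )


class TestConnectivity:
    def test_hand_computed_absolute_row_sums(self):
        A = np.zeros((3, 3))
        A[0, 1] = A[1, 0] = 0.5
        A[0, 2] = A[2, 0] = -0.8
        np.testing.assert_allclose(connectivity(A).chi, [1.3, 0.5, 0.8])

    def test_empty_network_has_zero_connectivity(self):
        assert np.all(connectivity(np.zeros((5, 5))).chi == 0)

    def test_fully_connected_unweighted_reaches_upper_bound(self):
        p = 7
        A = np.ones((p, p))
        np.testing.assert_allclose(connectivity(A).chi, p - 1)

    @given(arrays(np.float64, (6, 6), elements=st.floats(-1, 1, allow_nan=False)))
    def test_bounds_on_correlation_weighted_networks(self, mat):
        A = (mat + mat.T) / 2
        chi = connectivity(A).chi
        assert np.all(chi >= 0)
        assert np.all(chi <= 6 - 1 + 1e-9)


class TestDifferentialConnectivity:
    def test_identical_networks_give_zero(self):
        rng = np.random.default_rng(0)
        A = rng.uniform(-1, 1, (5, 5))
        net = _net((A + A.T) / 2)
        assert np.all(differential_connectivity(net, net) == 0)

    def test_antisymmetric_under_swap(self):
        rng = np.random.default_rng(1)
        A = (lambda m: (m + m.T) / 2)(rng.uniform(-1, 1, (5, 5)))
        B = (lambda m: (m + m.T) / 2)(rng.uniform(-1, 1, (5, 5)))
        nA, nB = _net(A), _net(B)
        np.testing.assert_allclose(
            differential_connectivity(nA, nB), -differential_connectivity(nB, nA)
        )

    def test_direct_subtraction(self):
        A = np.zeros((2, 2))
        A[0, 1] = A[1, 0] = 0.5
        nB = _net(A)
        A2 = np.zeros((2, 2))
        A2[0, 1] = A2[1, 0] = 0.5
        nA = _net(A2 * 4)  # chi_A = (2.0, 2.0)
        delta = differential_connectivity(nA, nB)
        np.testing.assert_allclose(delta, [1.5, 1.5])

    def test_label_mismatch_rejected(self):
        a = _net(np.zeros((3, 3)))
        b = _net(np.zeros((3, 3)))
        b.features = ["x", "y", "z"]
        with pytest.raises(ValueError):
            differential_connectivity(a, b)


class TestPermutationPvalues:
    def test_floor_is_one_over_k(self):
        delta = np.array([10.0])
        null = np.zeros((1, 100))
        p = _permutation_pvalues(delta, null, 100, "strict")
        assert p[0] == pytest.approx(0.01)

    def test_hand_case_four_exceedances(self):
        delta = np.array([1.0])
        null = np.zeros((1, 100))
        null[0, :4] = 2.0  # 4 null values exceed |delta|
        p = _permutation_pvalues(delta, null, 100, "strict")
        assert p[0] == pytest.approx(0.05)

    def test_tie_handling_modes(self):
        delta = np.array([1.0])
        null = np.full((1, 10), 1.0)  # all ties
        assert _permutation_pvalues(delta, null, 10, "strict")[0] == pytest.approx(0.1)
        assert _permutation_pvalues(delta, null, 10, "conservative")[0] == 1.0

    def test_capped_at_one(self):
        delta = np.array([0.0])
        null = np.ones((1, 10))
        assert _permutation_pvalues(delta, null, 10, "strict")[0] == 1.0


class TestBhAdjust:
    def test_textbook_case(self):
        np.testing.assert_allclose(
            bh_adjust(np.array([0.01, 0.02, 0.03, 0.04])), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_and_equal_values_unchanged(self):
        assert bh_adjust(np.array([0.37]))[0] == pytest.approx(0.37)
        np.testing.assert_allclose(bh_adjust(np.full(5, 0.2)), 0.2)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust(np.array([0.1, 1.5]))
        with pytest.raises(ValueError):
            bh_adjust(np.array([np.nan]))

    @given(
        arrays(
            np.float64,
            st.integers(1, 30),
            elements=st.floats(0, 1, allow_nan=False),
        )
    )
    def test_matches_bruteforce_stepup(self, p):
        adjusted = bh_adjust(p)
        np.testing.assert_allclose(adjusted, _bruteforce_bh(p), atol=1e-12)
        assert np.all(adjusted >= p - 1e-12)
        assert np.all((adjusted >= 0) & (adjusted <= 1))


def _bruteforce_bh(p: np.ndarray) -> np.ndarray:
    """Textbook step-up: p_(i) * m / i with right-to-left running minimum."""
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adjusted = np.empty(m)
    running = 1.0
    for rank_from_top in range(m, 0, -1):
        idx = order[rank_from_top - 1]
        running = min(running, p[idx] * m / rank_from_top)
        adjusted[idx] = running
    return adjusted


@pytest.fixture(scope="module")
def planted_result():
    rng = np.random.default_rng(2)
    n, p = 120, 8
    XA = rng.standard_normal((n, p))
    XA[:, 1] = XA[:, 0] + 0.05 * rng.standard_normal(n)  # tight pair in A only
    XB = rng.standard_normal((n, p))
    cfg = PclrcConfig(n_iterations=40, seed=3)
    return permutation_test(XA, XB, cfg, k=20, seed=4)


class TestPermutationTest:
    def test_detects_planted_group_difference(self, planted_result):
        res = planted_result
        assert res.delta[0] > 0.5 and res.delta[1] > 0.5
        assert res.pvalues[0] == pytest.approx(1 / res.k)

    def test_result_invariants(self, planted_result):
        res = planted_result
        p = len(res.features)
        assert res.null.shape == (p, res.k)
        assert np.all(res.pvalues >= 1 / res.k - 1e-12)
        assert np.all(res.pvalues <= 1.0)
        assert np.all(res.adjusted_pvalues >= res.pvalues - 1e-12)
        assert np.all(np.abs(res.delta) <= p - 1)
        np.testing.assert_allclose(res.delta, res.chi_a - res.chi_b)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(5)
        XA = rng.standard_normal((50, 5))
        XB = rng.standard_normal((60, 5))
        cfg = PclrcConfig(n_iterations=10, seed=0)
        r1 = permutation_test(XA, XB, cfg, k=5, seed=9)
        r2 = permutation_test(XA, XB, cfg, k=5, seed=9)
        np.testing.assert_array_equal(r1.null, r2.null)
        np.testing.assert_array_equal(r1.pvalues, r2.pvalues)

    def test_feature_count_mismatch_rejected(self):
        with pytest.raises(ValueError):
            permutation_test(np.ones((10, 3)), np.ones((10, 4)), k=2)


class TestPairwiseFrequency:
    def test_number_of_comparisons_and_retention_rule(self, monkeypatch):
        # stub the per-pair test: feature 0 significant in every pair,
        # feature 1 in exactly 7/10 (boundary: NOT retained), feature 2 never
        calls = {"i": 0}

        class FakeResult:
            def __init__(self, adjusted):
                self.adjusted_pvalues = adjusted

        def fake_permutation_test(a, b, cfg, k, seed, perm_cfg=None, **kw):
            i = calls["i"]
            calls["i"] += 1
            adj = np.array([0.01, 0.01 if i < 7 else 0.5, 0.9])
            return FakeResult(adj)

        import covnet.diffconn as dc

        monkeypatch.setattr(dc, "permutation_test", fake_permutation_test)
        datasets = {f"net{i}": np.zeros((10, 3)) for i in range(5)}
        out = dc.pairwise_significance_frequency(datasets, k=10, seed=0)
        assert calls["i"] == 10  # C(5, 2)
        assert out["n_comparisons"].iloc[0] == 10
        np.testing.assert_allclose(out["frequency"], [1.0, 0.7, 0.0])
        assert list(out["retained"]) == [True, False, False]

    def test_requires_two_networks(self):
        with pytest.raises(ValueError):
            pairwise_significance_frequency({"only": np.zeros((5, 2))})

    def test_end_to_end_on_tiny_category(self):
        rng = np.random.default_rng(6)
        n, p = 60, 5
        base = rng.standard_normal((n, p))
        datasets = {
            "m1": base + 0.01 * rng.standard_normal((n, p)),
            "m2": rng.standard_normal((n, p)),
            "m3": rng.standard_normal((n, p)),
        }
        cfg = PclrcConfig(n_iterations=10, seed=0)
        out = pairwise_significance_frequency(datasets, cfg, k=5, seed=1)
        assert len(out) == p
        assert out["n_comparisons"].iloc[0] == 3
        assert np.all((out["frequency"] >= 0) & (out["frequency"] <= 1))
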