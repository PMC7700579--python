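import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from agglomnet.gravity_network import (
    GravityMatrix,
    SpatialNetwork,
    binarize,
    modified_gravity,
    traditional_gravity,
)


def _dist(n, rng=None, scale=100.0):
    rng = rng or np.random.default_rng(0)
    pts = rng.random((n, 2)) * scale
    d = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
    np.fill_diagonal(d, 0.0)
    return d


class TestTraditionalGravity:
    def test_unit_case(self):
        D = np.array([[0.0, 1.0], [1.0, 0.0]])
        X = traditional_gravity(np.ones(2), np.ones(2), D, lam=1.0)
        assert X[0, 1] == pytest.approx(1.0)
        assert X[1, 0] == pytest.approx(1.0)
        assert X[0, 0] == 0.0

    def test_inverse_square(self):
        D = np.array([[0.0, 1.0], [1.0, 0.0]])
        X1 = traditional_gravity(np.ones(2), np.ones(2), D)
        X2 = traditional_gravity(np.ones(2), np.ones(2), 2 * D)
        np.testing.assert_allclose(X2[0, 1], X1[0, 1] / 4)

    def test_three_region_oracle(self, rng):
        P = rng.lognormal(1, 0.3, 3)
        G = rng.lognormal(2, 0.3, 3)
        D = _dist(3, rng)
        X = traditional_gravity(P, G, D, lam=0.7)
        for e in range(3):
            for f in range(3):
                if e == f:
                    assert X[e, f] == 0.0
                else:
                    assert X[e, f] == pytest.approx(
                        0.7 * P[e] * G[e] * P[f] * G[f] / D[e, f] ** 2
                    )

    def test_symmetry(self, rng):
        X = traditional_gravity(rng.lognormal(size=4), rng.lognormal(size=4), _dist(4, rng))
        np.testing.assert_allclose(X, X.T)

    def test_nonpositive_rejected(self):
        D = np.array([[0.0, 1.0], [1.0, 0.0]])
        with pytest.raises(ValueError):
            traditional_gravity(np.array([1.0, 0.0]), np.ones(2), D)

    def test_zero_distance_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            traditional_gravity(np.ones(2), np.ones(2), np.zeros((2, 2)))


class TestModifiedGravity:
    def test_lambda_half_when_equal_capacity(self):
        D = _dist(3)
        gm = modified_gravity(np.ones(3), np.ones(3), np.array([1.0, 2.0, 3.0]), np.ones(3), D)
        off = ~np.eye(3, dtype=bool)
        np.testing.assert_allclose(gm.lam[off], 0.5)

    def test_lambda_complement(self, rng):
        n = 6
        gm = modified_gravity(
            rng.lognormal(size=n),
            rng.lognormal(size=n),
            rng.lognormal(size=n),
            rng.lognormal(size=n),
            _dist(n, rng),
        )
        off = ~np.eye(n, dtype=bool)
        np.testing.assert_allclose((gm.lam + gm.lam.T)[off], 1.0, atol=1e-12)

    def test_equal_pc_gdp_vanishes_under_floor(self):
        D = _dist(3)
        g = np.array([2.0, 2.0, 5.0])
        gm = modified_gravity(np.ones(3), np.ones(3), g, np.ones(3), D)
        # pair (0,1) has identical per-capita GDP: cell floored near zero
        assert gm.values[0, 1] < 1e-6 * gm.values[0, 2]

    def test_four_region_bruteforce(self, rng):
        n = 4
        P, G, g, N = (rng.lognormal(1, 0.5, n) for _ in range(4))
        D = _dist(n, rng)
        gm = modified_gravity(P, G, g, N, D)
        for e in range(n):
            for f in range(n):
                if e == f:
                    assert gm.values[e, f] == 0.0
                    continue
                lam = N[e] / (N[e] + N[f])
                expect = (
                    lam
                    * np.cbrt(P[e] * N[e] * G[e])
                    * np.cbrt(P[f] * N[f] * G[f])
                    * abs(g[e] - g[f])
                    / D[e, f]
                )
                assert gm.values[e, f] == pytest.approx(expect, rel=1e-12)

    @given(st.integers(0, 1000))
    @settings(max_examples=25, deadline=None)
    def test_ten_region_oracle_property(self, seed):
        rng = np.random.default_rng(seed)
        n = 10
        P, G, g, N = (rng.lognormal(1, 0.5, n) for _ in range(4))
        D = _dist(n, rng)
        gm = modified_gravity(P, G, g, N, D)
        # naive double loop
        expect = np.zeros((n, n))
        floor = 1e-9 * g.mean()
        for e in range(n):
            for f in range(n):
                if e != f:
                    expect[e, f] = (
                        N[e] / (N[e] + N[f])
                        * np.cbrt(P[e] * N[e] * G[e])
                        * np.cbrt(P[f] * N[f] * G[f])
                        * max(abs(g[e] - g[f]), floor)
                        / D[e, f]
                    )
        np.testing.assert_allclose(gm.values, expect, rtol=1e-12)

    def test_nonpositive_rejected(self):
        D = _dist(3)
        with pytest.raises(ValueError, match="capacity"):
            modified_gravity(np.ones(3), np.ones(3), np.ones(3), np.array([1, 1, 0.0]), D)


class TestBinarize:
    def test_constant_positive_complete(self):
        X = np.full((4, 4), 3.0)
        np.fill_diagonal(X, 0.0)
        net = binarize(X)
        off = ~np.eye(4, dtype=bool)
        assert net.adjacency[off].all()
        assert np.diag(net.adjacency).sum() == 0

    def test_all_zero_empty(self):
        net = binarize(np.zeros((5, 5)))
        assert net.adjacency.sum() == 0

    def test_dominant_row_entry(self):
        X = np.array(
            [
                [0.0, 100.0, 1.0, 1.0],
                [1.0, 0.0, 1.0, 1.0],
                [1.0, 1.0, 0.0, 1.0],
                [1.0, 1.0, 1.0, 0.0],
            ]
        )
        net = binarize(X, rule="row_mean")
        # row 0 mean = 34: only the dominant cell survives
        np.testing.assert_array_equal(net.adjacency[0], [0, 1, 0, 0])
        # other rows are constant: all their cells survive
        assert net.adjacency[1].sum() == 3

    @given(st.integers(0, 500), st.floats(0.1, 50.0))
    @settings(max_examples=40, deadline=None)
    def test_scale_invariance_row_mean(self, seed, c):
        rng = np.random.default_rng(seed)
        X = rng.lognormal(0, 1, (6, 6))
        np.fill_diagonal(X, 0.0)
        a = binarize(X, rule="row_mean").adjacency
        b = binarize(c * X, rule="row_mean").adjacency
        np.testing.assert_array_equal(a, b)

    def test_rule_equivalence_on_symmetric(self, rng):
        X = rng.lognormal(0, 1, (5, 5))
        X = X + X.T
        np.fill_diagonal(X, 0.0)
        a_row = binarize(X, rule="row_mean").adjacency
        a_col = binarize(X, rule="col_mean").adjacency
        np.testing.assert_array_equal(a_row, a_col.T)

    def test_grand_mean_rule(self):
        X = np.array([[0.0, 10.0], [1.0, 0.0]])
        net = binarize(X, rule="grand_mean")
        np.testing.assert_array_equal(net.adjacency, [[0, 1], [0, 0]])

    def test_unknown_rule(self):
        with pytest.raises(ValueError, match="unknown binarization rule"):
            binarize(np.zeros((3, 3)), rule="median")

    def test_gravity_matrix_input_keeps_ids(self):
        gm = GravityMatrix(
            values=np.array([[0.0, 2.0], [1.0, 0.0]]),
            lam=np.array([[0.0, 0.5], [0.5, 0.0]]),
            region_ids=["x", "y"],
        )
        net = binarize(gm)
        assert net.region_ids == ["x", "y"]


class TestSpatialNetwork:
    def test_rejects_self_ties(self):
        with pytest.raises(ValueError, match="self-ties"):
            SpatialNetwork(np.eye(3, dtype=int), ["a", "b", "c"])

    def test_rejects_non_binary(self):
        with pytest.raises(ValueError, match="0 or 1"):
            SpatialNetwork(np.full((2, 2), 2), ["a", "b"])
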