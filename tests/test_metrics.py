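"""Graph measures: hand-computed examples, brute-force oracles, invariances."""

import numpy as np
import pytest

from lobeconn.metrics import (
    auc,
    betweenness,
    clustering,
    efficiency,
    metrics_over_costs,
    rewire_preserving_degree,
    small_worldness,
    strength_total,
)
from lobeconn.connectome import WeightedConnectome

from oracles import brute_betweenness, brute_clustering, brute_efficiency, random_connected_graph


def graph(edges, n):
    w = np.zeros((n, n))
    for i, j, v in edges:
        w[i, j] = w[j, i] = v
    return w


UNIT_TRIANGLE = graph([(0, 1, 1), (1, 2, 1), (0, 2, 1)], 3)
UNIT_P3 = graph([(0, 1, 1), (1, 2, 1)], 3)
UNIT_STAR5 = graph([(0, i, 1) for i in range(1, 5)], 5)


class TestStrength:
    def test_unit_triangle(self):
        assert strength_total(UNIT_TRIANGLE) == 3.0

    def test_empty_graph(self):
        assert strength_total(np.zeros((4, 4))) == 0.0

    def test_half_of_full_adjacency_sum(self, rng):
        w = np.abs(rng.standard_normal((6, 6)))
        w = np.triu(w, 1) + np.triu(w, 1).T
        assert strength_total(w) == pytest.approx(w.sum() / 2)


class TestClustering:
    def test_unit_complete_graph(self):
        k4 = graph([(i, j, 1) for i in range(4) for j in range(i + 1, 4)], 4)
        c_i, c_net = clustering(k4)
        assert np.allclose(c_i, 1.0)
        assert c_net == pytest.approx(1.0)

    def test_star_has_no_triangles(self):
        c_i, c_net = clustering(UNIT_STAR5)
        assert np.allclose(c_i, 0.0)
        assert c_net == 0.0

    def test_max_normalisation_makes_uniform_triangle_perfect(self):
        c_i, _ = clustering(0.5 * UNIT_TRIANGLE)
        assert np.allclose(c_i, 1.0)

    def test_scale_invariance(self, rng):
        w = random_connected_graph(rng, 6)
        _, a = clustering(w)
        _, b = clustering(3.7 * w)
        assert a == pytest.approx(b, rel=1e-12)


class TestEfficiency:
    def test_unit_complete_graph(self):
        k5 = graph([(i, j, 1) for i in range(5) for j in range(i + 1, 5)], 5)
        _, e_net = efficiency(k5)
        assert e_net == pytest.approx(1.0)

    def test_unit_path_three_nodes(self):
        # ordered-pair distances: 1,1,1,1,2,2 -> E = 5/6
        _, e_net = efficiency(UNIT_P3)
        assert e_net == pytest.approx(5 / 6)

    def test_disconnected_pairs_contribute_zero(self):
        w = graph([(0, 1, 1), (2, 3, 1)], 4)
        _, e_net = efficiency(w)
        assert e_net == pytest.approx(1 / 3)


class TestBetweenness:
    def test_path_center_mediates_one_pair(self):
        assert list(betweenness(UNIT_P3)) == [0.0, 1.0, 0.0]

    def test_star_hub_mediates_all_leaf_pairs(self):
        bc = betweenness(UNIT_STAR5)
        assert bc[0] == 6.0  # C(4,2)
        assert np.all(bc[1:] == 0.0)

    def test_cycle_is_vertex_transitive(self):
        c4 = graph([(0, 1, 1), (1, 2, 1), (2, 3, 1), (3, 0, 1)], 4)
        bc = betweenness(c4)
        assert np.allclose(bc, bc[0])


class TestBruteForceOracle:
    @pytest.mark.parametrize("seed", range(10))
    def test_efficiency_and_clustering_match_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 8))
        w = random_connected_graph(rng, n)
        e_i, e_net = efficiency(w)
        be_i, be_net = brute_efficiency(w)
        assert np.allclose(e_i, be_i, atol=1e-9)
        c_i, c_net = clustering(w)
        bc_i, bc_net = brute_clustering(w)
        assert np.allclose(c_i, bc_i, atol=1e-12)

    @pytest.mark.parametrize("seed", range(10))
    def test_betweenness_matches_geodesic_counting(self, seed):
        rng = np.random.default_rng(100 + seed)
        n = int(rng.integers(4, 8))
        w = random_connected_graph(rng, n, dyadic=True)
        assert np.allclose(betweenness(w), brute_betweenness(w), atol=1e-9)


class TestPermutationEquivariance:
    def test_nodal_metrics_permute_global_invariant(self, rng):
        w = random_connected_graph(rng, 7)
        perm = rng.permutation(7)
        wp = w[np.ix_(perm, perm)]
        e_i, e_net = efficiency(w)
        ep_i, ep_net = efficiency(wp)
        assert np.allclose(ep_i, e_i[perm])
        assert e_net == pytest.approx(ep_net)
        assert np.allclose(betweenness(wp), betweenness(w)[perm])
        assert strength_total(w) == pytest.approx(strength_total(wp))


class TestSmallWorldness:
    def test_dense_random_graph_is_its_own_null(self, rng):
        n = 30
        w = np.where(rng.random((n, n)) < 0.6, rng.uniform(0.5, 1.0, (n, n)), 0)
        w = np.triu(w, 1) + np.triu(w, 1).T
        sigma = small_worldness(w, n_null=30, rng=0)
        assert 0.75 < sigma < 1.3

    def test_ring_lattice_with_shortcuts_is_small_world(self):
        n = 50
        w = np.zeros((n, n))
        for i in range(n):
            for step in (1, 2):  # k=4 neighbours
                j = (i + step) % n
                w[i, j] = w[j, i] = 1.0
        rng = np.random.default_rng(3)
        for _ in range(5):  # ~5% shortcuts
            i, j = rng.integers(0, n, 2)
            if i != j:
                w[i, j] = w[j, i] = 1.0
        assert small_worldness(w, n_null=20, rng=1) > 1.0

    def test_reproducible_given_seed(self, rng):
        w = random_connected_graph(rng, 12)
        assert small_worldness(w, n_null=1, rng=42) == small_worldness(w, n_null=1, rng=42)

    def test_triangle_free_graph_degenerate_null(self):
        with pytest.raises(ValueError, match="denser"):
            small_worldness(UNIT_P3, n_null=3, rng=0)

    def test_rewiring_preserves_degrees_and_weights(self, rng):
        w = random_connected_graph(rng, 12)
        null = rewire_preserving_degree(w, np.random.default_rng(5))
        assert np.array_equal((null > 0).sum(axis=0), (w > 0).sum(axis=0))
        assert np.allclose(np.sort(null[null > 0]), np.sort(w[w > 0]))


class TestAuc:
    def test_constant_curve(self):
        x = np.round(np.arange(0.10, 0.351, 0.01), 2)
        assert auc(x, np.full(len(x), 2.0)) == pytest.approx(0.5)

    def test_linear_two_points(self):
        assert auc([0.0, 1.0], [0.0, 1.0]) == pytest.approx(0.5)

    def test_matches_piecewise_linear_oracle(self, rng):
        x = np.round(np.arange(0.10, 0.351, 0.01), 2)
        y = rng.standard_normal(len(x))
        # independent piecewise-linear integration, segment by segment
        exact = sum(
            (y[k] + y[k + 1]) / 2.0 * (x[k + 1] - x[k]) for k in range(len(x) - 1)
        )
        assert auc(x, y) == pytest.approx(exact, abs=1e-12)
        # and a midpoint Riemann sum on a fine grid agrees to its own accuracy
        fine = np.linspace(x[0], x[-1], 100001)
        mids = (fine[:-1] + fine[1:]) / 2
        riemann = np.sum(np.interp(mids, x, y) * np.diff(fine))
        assert auc(x, y) == pytest.approx(riemann, abs=1e-7)

    def test_unsorted_grid_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            auc([0.2, 0.1], [1.0, 1.0])


class TestMetricsOverCosts:
    def _conn(self, rng, n=16):
        w = np.abs(rng.standard_normal((n, n)))
        w = np.triu(w, 1) + np.triu(w, 1).T
        return WeightedConnectome("w", w)

    def test_default_grid_has_26_points(self, rng):
        prof = metrics_over_costs(self._conn(rng), nodal=False)
        assert len(prof.costs) == 26
        assert set(prof.global_curves) == {"S_net", "C_net", "E_net"}

    def test_grid_subset_is_pointwise_consistent(self, rng):
        conn = self._conn(rng)
        full = metrics_over_costs(conn, np.round(np.arange(0.2, 0.41, 0.05), 2))
        sub = metrics_over_costs(conn, np.round(np.arange(0.2, 0.31, 0.05), 2))
        assert np.allclose(sub.global_curves["E_net"].y, full.global_curves["E_net"].y[:3])
        assert np.allclose(sub.nodal_curves["C_i"], full.nodal_curves["C_i"][:3])

    def test_single_point_grid_warns_and_zeroes_auc(self, rng, caplog):
        with caplog.at_level("WARNING"):
            prof = metrics_over_costs(self._conn(rng), [0.2])
        assert prof.global_curves["S_net"].auc == 0.0
        assert any("single-point" in r.message for r in caplog.records)

    def test_strength_and_efficiency_monotone_in_cost(self, rng):
        prof = metrics_over_costs(self._conn(rng), nodal=False)
        assert np.all(np.diff(prof.global_curves["S_net"].y) >= 0)
        assert np.all(np.diff(prof.global_curves["E_net"].y) >= -1e-12)
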