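"""Graph metrics against brute-force enumeration oracles and worked values."""

import itertools

import networkx as nx
import numpy as np
import pytest

from nirsfc.network import (
    AdjacencyMatrix,
    _modularity_q,
    betweenness,
    characteristic_path_length,
    clustering_coefficient,
    compute_metrics,
    efficiencies,
    hierarchy,
    hierarchy_fit,
    modularity,
    random_rewire,
    small_world,
    sparsity_sweep,
    threshold_matrix,
)


def adj_from_edges(n, edges, weights=None):
    w = np.zeros((n, n))
    for k, (i, j) in enumerate(edges):
        w[i, j] = w[j, i] = 1.0 if weights is None else weights[k]
    return AdjacencyMatrix(weights=w, mode="binary" if weights is None else "weighted")


# ---------------------------------------------------------------------------
# brute-force oracles (independent of the implementation path)
# ---------------------------------------------------------------------------

def brute_distances(a):
    """All-pairs shortest paths by explicit breadth-first search."""
    n = a.shape[0]
    d = np.full((n, n), np.inf)
    for s in range(n):
        d[s, s] = 0
        frontier = [s]
        level = 0
        while frontier:
            level += 1
            nxt = []
            for u in frontier:
                for v in np.flatnonzero(a[u]):
                    if d[s, v] == np.inf:
                        d[s, v] = level
                        nxt.append(v)
            frontier = nxt
    return d

def brute_clustering(a):
    n = a.shape[0]
    c = np.zeros(n)
    for i in range(n):
        nbrs = np.flatnonzero(a[i])
        k = nbrs.size
        if k < 2:
            continue
        links = sum(a[u, v] > 0 for u, v in itertools.combinations(nbrs, 2))
        c[i] = 2.0 * links / (k * (k - 1))
    return c

def brute_betweenness(a):
    """Fractional shortest-path counting by explicit path enumeration."""
    n = a.shape[0]
    d = brute_distances(a)
    bc = np.zeros(n)
    for s, t in itertools.permutations(range(n), 2):
        if not np.isfinite(d[s, t]):
            continue
        paths = []
        stack = [[s]]
        while stack:
            path = stack.pop()
            u = path[-1]
            if u == t:
                paths.append(path)
                continue
            if len(path) - 1 >= d[s, t]:
                continue
            for v in np.flatnonzero(a[u]):
                if v not in path and d[s, v] == len(path) and \
                        d[s, v] + d[v, t] == d[s, t]:
                    stack.append(path + [int(v)])
        for path in paths:
            for v in path[1:-1]:
                bc[v] += 1.0 / len(paths)
    return bc / 2.0  # each undirected pair counted in both directions

def brute_modularity(a):
    """Exhaustive search over all partitions (labels via product, n <= 8)."""
    n = a.shape[0]
    best = -np.inf
    for labels in itertools.product(range(n), repeat=n):
        q = _modularity_q(a, np.array(labels))
        best = max(best, q)
    return best


class TestWorkedValues:
    def test_triangle_fully_clustered(self):
        cp, _ = clustering_coefficient(adj_from_edges(3, [(0, 1), (1, 2), (0, 2)]))
        assert cp == 1.0

    def test_star_unclustered(self):
        star = adj_from_edges(5, [(0, i) for i in range(1, 5)])
        cp, _ = clustering_coefficient(star)
        assert cp == 0.0

    def test_k4_minus_edge_clustering(self):
        edges = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3)]  # missing (2,3)
        cp, _ = clustering_coefficient(adj_from_edges(4, edges))
        assert cp == pytest.approx(5.0 / 6.0, abs=1e-12)

    def test_six_cycle_path_length(self):
        cyc = adj_from_edges(6, [(i, (i + 1) % 6) for i in range(6)])
        lp, frac = characteristic_path_length(cyc)
        assert lp == pytest.approx(1.8, abs=1e-12)
        assert frac == 0.0

    def test_complete_graph_unit_path_and_efficiency(self):
        k5 = adj_from_edges(5, list(itertools.combinations(range(5), 2)))
        lp, _ = characteristic_path_length(k5)
        eglob, eloc, _ = efficiencies(k5)
        assert lp == 1.0
        assert eglob == 1.0
        assert eloc == 1.0

    def test_six_cycle_global_efficiency(self):
        cyc = adj_from_edges(6, [(i, (i + 1) % 6) for i in range(6)])
        eglob, _, _ = efficiencies(cyc)
        assert eglob == pytest.approx((1 + 1 + 0.5 + 0.5 + 1 / 3) / 5, abs=1e-12)

    def test_empty_graph_zero_efficiency(self):
        eglob, eloc, nodal = efficiencies(AdjacencyMatrix(np.zeros((4, 4))))
        assert eglob == 0.0
        np.testing.assert_array_equal(nodal, 0.0)

    def test_two_isolated_edges_disconnection(self):
        two = adj_from_edges(4, [(0, 1), (2, 3)])
        lp, frac = characteristic_path_length(two)
        assert lp == 1.0
        assert frac == pytest.approx(2.0 / 3.0)

    def test_path_graph_betweenness(self):
        path = adj_from_edges(3, [(0, 1), (1, 2)])
        np.testing.assert_allclose(betweenness(path), [0.0, 1.0, 0.0])

    def test_star_center_betweenness(self):
        star = adj_from_edges(5, [(0, i) for i in range(1, 5)])
        bc = betweenness(star)
        assert bc[0] == pytest.approx(6.0)  # C(4,2)
        np.testing.assert_allclose(bc[1:], 0.0)

    def test_complete_graph_zero_betweenness(self):
        k5 = adj_from_edges(5, list(itertools.combinations(range(5), 2)))
        np.testing.assert_allclose(betweenness(k5), 0.0)

    def test_two_triangles_bridge_modularity(self):
        edges = [(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5), (2, 3)]
        q, labels = modularity(adj_from_edges(6, edges), seed=1)
        assert q == pytest.approx(5.0 / 14.0, abs=1e-12)
        assert len(set(labels[:3])) == 1 and len(set(labels[3:])) == 1
        assert labels[0] != labels[3]

    def test_two_disconnected_triangles_modularity(self):
        edges = [(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)]
        q, _ = modularity(adj_from_edges(6, edges), seed=1)
        assert q == pytest.approx(0.5, abs=1e-12)

    def test_complete_graph_single_community(self):
        k5 = adj_from_edges(5, list(itertools.combinations(range(5), 2)))
        q, labels = modularity(k5, seed=1)
        assert q == pytest.approx(0.0, abs=1e-12)
        assert len(set(labels)) == 1

    def test_edgeless_graph_undefined_modularity(self):
        q, _ = modularity(AdjacencyMatrix(np.zeros((4, 4))), seed=1)
        assert np.isnan(q)


class TestHierarchy:
    def test_exact_power_law(self):
        k = np.array([2.0, 4.0, 8.0, 16.0])
        c = k ** -0.5
        beta, n = hierarchy_fit(k, c)
        assert beta == pytest.approx(0.5, abs=1e-12)
        assert n == 4

    def test_flat_clustering_zero_exponent(self):
        beta, _ = hierarchy_fit(np.array([2.0, 3, 4, 5]), np.full(4, 0.3))
        assert beta == pytest.approx(0.0, abs=1e-12)

    def test_degenerate_degrees_undefined(self):
        # all degrees equal: no slope identifiable
        beta, _ = hierarchy_fit(np.full(5, 4.0), np.linspace(0.2, 0.4, 5))
        assert np.isnan(beta)

    def test_graph_level_entry_point(self):
        k5 = adj_from_edges(5, list(itertools.combinations(range(5), 2)))
        beta, n = hierarchy(k5)
        assert np.isnan(beta)  # identical degrees
        assert n == 5


class TestThreshold:
    def test_full_sparsity_complete_graph(self):
        fc = np.full((5, 5), 0.5)
        adj = threshold_matrix(fc, sparsity=0.999, mode="binary")
        assert adj.n_edges == 10

    def test_top_k_selection(self):
        fc = np.zeros((4, 4))
        vals = {(0, 1): 0.9, (0, 2): 0.8, (0, 3): 0.7,
                (1, 2): 0.6, (1, 3): 0.5, (2, 3): 0.4}
        for (i, j), v in vals.items():
            fc[i, j] = fc[j, i] = v
        adj = threshold_matrix(fc, sparsity=0.5, mode="binary")
        assert adj.n_edges == 3
        assert adj.weights[0, 1] == 1 and adj.weights[0, 2] == 1 \
            and adj.weights[0, 3] == 1
        assert adj.weights[2, 3] == 0

    def test_negative_only_matrix_warns_empty(self):
        fc = -np.abs(np.random.default_rng(0).standard_normal((4, 4)))
        fc = (fc + fc.T) / 2
        with pytest.warns(UserWarning, match="positive"):
            adj = threshold_matrix(fc, sparsity=0.5)
        assert adj.n_edges == 0

    def test_weighted_mode_retains_r(self):
        fc = np.zeros((3, 3))
        fc[0, 1] = fc[1, 0] = 0.7
        fc[1, 2] = fc[2, 1] = 0.3
        adj = threshold_matrix(fc, cutoff=0.2, mode="weighted")
        assert adj.weights[0, 1] == pytest.approx(0.7)
        assert adj.weights[1, 2] == pytest.approx(0.3)

    def test_bad_sparsity_rejected(self):
        with pytest.raises(ValueError, match="sparsity"):
            threshold_matrix(np.eye(4), sparsity=1.5)

    def test_diagonal_always_zeroed(self):
        adj = threshold_matrix(np.ones((4, 4)), cutoff=0.1)
        np.testing.assert_array_equal(np.diag(adj.weights), 0.0)


def random_graphs(n_graphs, rng, n_max=8):
    for _ in range(n_graphs):
        n = int(rng.integers(3, n_max + 1))
        p = rng.uniform(0.2, 0.9)
        a = (rng.random((n, n)) < p).astype(float)
        a = np.triu(a, 1)
        a = a + a.T
        yield AdjacencyMatrix(weights=a)


class TestOracleEquivalence:
    """Implementation vs independent brute-force enumeration on small graphs."""

    def test_metrics_match_enumeration(self, rng):
        for adj in random_graphs(40, rng):
            a = adj.binary
            d = brute_distances(a)
            # clustering
            cp, c = clustering_coefficient(adj)
            np.testing.assert_allclose(c, brute_clustering(a), atol=1e-12)
            # path length
            lp, frac = characteristic_path_length(adj)
            off = ~np.eye(a.shape[0], dtype=bool)
            finite = np.isfinite(d) & off
            if finite.any():
                np.testing.assert_allclose(lp, d[finite].mean(), atol=1e-12)
            # efficiencies
            eglob, eloc, nodal = efficiencies(adj)
            inv = np.where(finite, 1.0 / np.where(d == 0, np.inf, d), 0.0)
            np.testing.assert_allclose(eglob, inv.sum() / (off.sum()), atol=1e-12)
            np.testing.assert_allclose(nodal, inv.sum(axis=1) / (a.shape[0] - 1),
                                       atol=1e-12)
            # betweenness
            np.testing.assert_allclose(betweenness(adj), brute_betweenness(a),
                                       atol=1e-12)

    def test_modularity_matches_exhaustive_search(self, rng):
        for adj in random_graphs(15, rng, n_max=6):
            if adj.n_edges == 0:
                continue
            q, _ = modularity(adj, seed=7)
            assert q == pytest.approx(brute_modularity(adj.binary), abs=1e-12)


class TestRewireAndSmallWorld:
    def test_degree_sequence_preserved(self, rng):
        g = nx.erdos_renyi_graph(20, 0.3, seed=4)
        adj = AdjacencyMatrix(nx.to_numpy_array(g))
        null = random_rewire(adj, seed=9)
        np.testing.assert_array_equal(np.sort(null.degrees()),
                                      np.sort(adj.degrees()))
        np.testing.assert_array_equal(null.degrees(), adj.degrees())

    def test_rewire_deterministic(self):
        g = nx.erdos_renyi_graph(15, 0.4, seed=2)
        adj = AdjacencyMatrix(nx.to_numpy_array(g))
        a = random_rewire(adj, seed=5)
        b = random_rewire(adj, seed=5)
        np.testing.assert_array_equal(a.weights, b.weights)

    def test_rewiring_destroys_lattice_clustering(self):
        g = nx.watts_strogatz_graph(100, 10, 0.0, seed=0)  # pure ring lattice
        adj = AdjacencyMatrix(nx.to_numpy_array(g))
        cp_lattice, _ = clustering_coefficient(adj)
        null = random_rewire(adj, seed=3)
        cp_null, _ = clustering_coefficient(null)
        assert cp_null < cp_lattice

    def test_complete_graph_trivial_normalization(self):
        k6 = AdjacencyMatrix(1.0 - np.eye(6))
        gamma, lam, sigma = small_world(k6, n_random=5, seed=1)
        assert gamma == pytest.approx(1.0)
        assert lam == pytest.approx(1.0)
        assert sigma == pytest.approx(1.0)

    def test_random_graph_self_normalizes(self):
        g = nx.erdos_renyi_graph(40, 0.3, seed=8)
        adj = AdjacencyMatrix(nx.to_numpy_array(g))
        gamma, lam, _ = small_world(adj, n_random=20, seed=6)
        assert gamma == pytest.approx(1.0, abs=0.15)
        assert lam == pytest.approx(1.0, abs=0.1)


class TestSweep:
    def _matrices(self, rng, n_sub=2, n=12):
        out = {}
        for s in range(n_sub):
            x = rng.standard_normal((n, 60))
            out[f"sub{s}"] = np.corrcoef(x)
        return out

    def test_row_count(self, rng):
        table = sparsity_sweep(self._matrices(rng), [0.1, 0.2, 0.3, 0.4, 0.5],
                               n_random=5, with_null=False)
        assert len(table) == 10

    def test_parallel_determinism(self, rng):
        mats = self._matrices(rng)
        t1 = sparsity_sweep(mats, [0.2, 0.4], n_random=5, seed=3, n_jobs=1)
        t4 = sparsity_sweep(mats, [0.2, 0.4], n_random=5, seed=3, n_jobs=4)
        import pandas as pd
        pd.testing.assert_frame_equal(t1, t4)

    def test_eglob_monotone_in_sparsity(self, rng):
        mats = self._matrices(rng, n_sub=1)
        table = sparsity_sweep(mats, [0.1, 0.2, 0.3, 0.4, 0.5],
                               n_random=0, with_null=False)
        eglob = table.sort_values("sparsity")["eglob"].to_numpy()
        assert np.all(np.diff(eglob) >= -1e-12)

    def test_failures_recorded_not_raised(self, rng):
        mats = self._matrices(rng)
        mats["bad"] = np.ones((3, 4))  # not square
        table = sparsity_sweep(mats, [0.2], with_null=False)
        bad = table[table["subject"] == "bad"]
        assert (bad["error"] != "").all()
        good = table[table["subject"] != "bad"]
        assert (good["error"] == "").all()
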