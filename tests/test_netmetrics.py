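"""Graph metrics against an independent brute-force oracle.

The oracle computes all-pairs shortest paths by Floyd-Warshall over
1/weight edge lengths and evaluates the efficiency, clustering and path
length formulas directly from their definitions, sharing no code with the
implementation under test.
"""

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from plvnet.netmetrics import (
    WeightedGraph, build_graph, clustering_and_pathlength, degree_matched_nulls,
    global_efficiency, local_efficiency, small_worldness, subject_graph_metrics,
    threshold,
)


# ---------------------------------------------------------------- oracle ---

def _floyd_warshall(weights):
    n = len(weights)
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    for i in range(n):
        for j in range(n):
            if weights[i, j] > 0:
                d[i, j] = 1.0 / weights[i, j]
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    return d


def _oracle_global_efficiency(weights):
    d = _floyd_warshall(weights)
    n = len(weights)
    total = sum(1.0 / d[i, j]
                for i in range(n) for j in range(n)
                if i != j and np.isfinite(d[i, j]))
    return total / (n * (n - 1))


def _oracle_local_efficiency(weights):
    n = len(weights)
    total = 0.0
    for i in range(n):
        nbrs = [j for j in range(n) if weights[i, j] > 0]
        m = len(nbrs)
        if m < 2:
            continue
        sub = weights[np.ix_(nbrs, nbrs)]
        d = _floyd_warshall(sub)
        acc = sum(1.0 / d[a, b]
                  for a in range(m) for b in range(m)
                  if a != b and np.isfinite(d[a, b]))
        total += acc / (m * (m - 1))
    return total / n


def _oracle_clustering(weights):
    # Onnela geometric-mean triangle clustering on max-normalized weights
    n = len(weights)
    w = weights / weights.max()
    out = 0.0
    for i in range(n):
        nbrs = [j for j in range(n) if weights[i, j] > 0]
        k = len(nbrs)
        if k < 2:
            continue
        acc = sum((w[i, a] * w[i, b] * w[a, b]) ** (1 / 3)
                  for ai, a in enumerate(nbrs) for b in nbrs[ai + 1:]
                  if weights[a, b] > 0)
        out += 2 * acc / (k * (k - 1))
    return out / n


def _oracle_pathlength(weights):
    d = _floyd_warshall(weights)
    off = ~np.eye(len(weights), dtype=bool)
    vals = d[off & np.isfinite(d)]
    return vals.mean()


def _random_graph(rng, n):
    w = np.zeros((n, n))
    iu, ju = np.triu_indices(n, 1)
    mask = rng.uniform(size=len(iu)) < 0.45
    w[iu[mask], ju[mask]] = rng.uniform(0.1, 1.0, size=mask.sum())
    return w + w.T


# ----------------------------------------------------------------- tests ---

class TestAgainstBruteForce:
    def test_all_metrics_match_enumeration_on_random_graphs(self):
        rng = np.random.default_rng(20)
        for _ in range(50):
            n = int(rng.integers(4, 13))
            w = _random_graph(rng, n)
            if not (w > 0).any():
                continue
            g = WeightedGraph([f"n{i}" for i in range(n)], w)
            assert global_efficiency(g) == pytest.approx(
                _oracle_global_efficiency(w), abs=1e-12)
            assert local_efficiency(g) == pytest.approx(
                _oracle_local_efficiency(w), abs=1e-12)
            c, l = clustering_and_pathlength(g)
            assert c == pytest.approx(_oracle_clustering(w), abs=1e-12)
            assert l == pytest.approx(_oracle_pathlength(w), abs=1e-12)


class TestClosedFormCases:
    def test_three_node_path(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = w[1, 2] = w[2, 1] = 1.0
        g = WeightedGraph(list("abc"), w)
        assert global_efficiency(g) == pytest.approx(5 / 6)
        c, l = clustering_and_pathlength(g)
        assert c == 0.0 and l == pytest.approx(4 / 3)

    def test_complete_graph(self):
        w = np.ones((5, 5))
        g = WeightedGraph(list("abcde"), w)
        assert global_efficiency(g) == pytest.approx(1.0)
        c, l = clustering_and_pathlength(g)
        assert c == pytest.approx(1.0) and l == pytest.approx(1.0)

    def test_triangle_local_efficiency_is_one(self):
        w = np.ones((3, 3))
        assert local_efficiency(WeightedGraph(list("abc"), w)) == pytest.approx(1.0)

    def test_star_local_efficiency_is_zero(self):
        w = np.zeros((5, 5))
        w[0, 1:] = w[1:, 0] = 1.0
        assert local_efficiency(WeightedGraph(list("abcde"), w)) == 0.0

    def test_isolated_node_contributes_zero(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 1.0
        g = WeightedGraph(list("abc"), w)
        assert global_efficiency(g) == pytest.approx(2 / 6)

    def test_ring_lattice_clustering_half(self):
        ring = nx.watts_strogatz_graph(20, 4, 0.0)
        w = nx.to_numpy_array(ring)
        c, _ = clustering_and_pathlength(
            WeightedGraph([str(i) for i in range(20)], w))
        assert c == pytest.approx(0.5)


class TestBuildAndThreshold:
    def test_pair_set_mode_structural_zero_count(self, pairset):
        rows = pd.DataFrame({"pair": pairset.names,
                             "plv": np.linspace(0.2, 0.8, 40)})
        g = build_graph(rows, pairset.electrodes())
        assert g.n_nodes == 14
        assert g.n_edges == 40
        total = 14 * 13 // 2
        assert total - g.n_edges == 51

    def test_asymmetric_matrix_rejected(self):
        w = np.zeros((3, 3))
        w[0, 1] = 0.5
        with pytest.raises(ValueError, match="symmetric|asymmetric"):
            build_graph(w, list("abc"))

    def test_density_point_one_keeps_43_of_435(self, rng):
        w = _random_graph(rng, 30) + 0.01
        np.fill_diagonal(w, 0)
        w = np.triu(w, 1) + np.triu(w, 1).T
        thr = threshold(WeightedGraph([str(i) for i in range(30)], w), 0.10)
        assert thr.n_edges == 43

    def test_density_one_is_identity(self, rng):
        w = _random_graph(rng, 8)
        g = WeightedGraph([str(i) for i in range(8)], w)
        assert np.array_equal(threshold(g, 1.0).weights, g.weights)

    def test_tie_break_is_lexicographic(self):
        w = np.zeros((4, 4))
        # edges (0,1) and (2,3) tie; (0,3) is strongest; keep 2 of 6 -> floor
        w[0, 1] = w[1, 0] = 0.5
        w[2, 3] = w[3, 2] = 0.5
        w[0, 3] = w[3, 0] = 0.9
        g = WeightedGraph(list("abcd"), w)
        thr = threshold(g, 2 / 6 + 1e-9)
        assert thr.weights[0, 3] == 0.9
        assert thr.weights[0, 1] == 0.5  # lexicographically before (2,3)
        assert thr.weights[2, 3] == 0.0

    def test_zero_edge_density_rejected(self):
        g = WeightedGraph(list("abc"), np.ones((3, 3)))
        with pytest.raises(ValueError):
            threshold(g, 1e-6)


class TestInvariances:
    def test_relabeling_leaves_metrics_unchanged(self, rng):
        w = _random_graph(rng, 9)
        g = WeightedGraph([f"n{i}" for i in range(9)], w)
        perm = rng.permutation(9)
        g2 = WeightedGraph([f"m{i}" for i in range(9)],
                           w[np.ix_(perm, perm)])
        assert global_efficiency(g) == pytest.approx(global_efficiency(g2), abs=1e-12)
        assert local_efficiency(g) == pytest.approx(local_efficiency(g2), abs=1e-12)

    def test_efficiency_monotone_under_edge_addition(self, rng):
        for _ in range(10):
            w = _random_graph(rng, 8)
            g = WeightedGraph([str(i) for i in range(8)], w)
            zero = np.argwhere(np.triu(w == 0, 1))
            if len(zero) == 0:
                continue
            i, j = zero[rng.integers(len(zero))]
            w2 = w.copy()
            w2[i, j] = w2[j, i] = 0.5
            g2 = WeightedGraph([str(i) for i in range(8)], w2)
            assert global_efficiency(g2) >= global_efficiency(g) - 1e-12


class TestNullsAndSigma:
    def test_nulls_preserve_degree_sequence(self, rng):
        w = _random_graph(rng, 12)
        g = WeightedGraph([str(i) for i in range(12)], w)
        base = nx.from_numpy_array(w)
        degrees = sorted(dict(base.degree()).values())
        # reimplement one null draw via the public API indirectly: the
        # C_rand/L_rand means must come from graphs with the same degrees,
        # checked by rebuilding a null with the same seed path
        c_rand, l_rand = degree_matched_nulls(g, n_random=5, rng=3)
        assert c_rand > 0 and l_rand > 0
        # direct check on networkx double_edge_swap behaviour
        h = base.copy()
        nx.double_edge_swap(h, nswap=20, max_tries=2000, seed=1)
        assert sorted(dict(h.degree()).values()) == degrees

    def test_sigma_identities(self):
        assert small_worldness(0.5, 2.0, 0.5, 2.0) == pytest.approx(1.0)
        assert small_worldness(1.0, 2.0, 0.5, 2.0) == pytest.approx(2.0)
        with pytest.raises(ValueError):
            small_worldness(1.0, 1.0, 0.0, 1.0)

    def test_watts_strogatz_is_small_world(self):
        sigmas = []
        for seed in range(3):
            ws = nx.watts_strogatz_graph(60, 6, 0.1, seed=seed)
            g = WeightedGraph([str(i) for i in range(60)],
                              nx.to_numpy_array(ws))
            c, l = clustering_and_pathlength(g)
            cr, lr = degree_matched_nulls(g, n_random=20, rng=seed)
            sigmas.append(small_worldness(c, l, cr, lr))
        assert np.mean(sigmas) > 1.0

    def test_subject_graph_metrics_panel(self, rng):
        w = _random_graph(rng, 20) + 0.05
        np.fill_diagonal(w, 0)
        w = np.triu(w, 1) + np.triu(w, 1).T
        panel = subject_graph_metrics(
            WeightedGraph([str(i) for i in range(20)], w),
            density=0.3, n_random=5, rng=0)
        assert set(panel) >= {"GE", "LE", "C", "L", "C_rand", "L_rand", "sigma"}
        assert panel["sigma"] == pytest.approx(
            (panel["C"] / panel["C_rand"]) / (panel["L"] / panel["L_rand"]))
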