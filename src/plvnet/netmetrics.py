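"""Graph construction from PLV matrices and graph-theoretic network metrics.

Graphs are weighted and undirected. Shortest-path edge length is 1/weight
(the standard convention for coherence weights, so stronger coupling means
shorter distance). Global efficiency is the mean of 1/d over ordered node
pairs with disconnected pairs contributing 0; local efficiency applies the
same quantity to each node's neighbor-induced subgraph. Clustering is the
Onnela geometric-mean triangle formula on weights normalized by the maximum
weight; characteristic path length is the mean distance over connected
ordered pairs. Small-worldness sigma = (C/C_rand)/(L/L_rand) against
degree-matched Maslov-Sneppen rewired nulls with weights re-permuted over
the rewired edge set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.sparse.csgraph import dijkstra

log = logging.getLogger(__name__)

__all__ = [
    "WeightedGraph", "build_graph", "threshold", "global_efficiency",
    "local_efficiency", "clustering_and_pathlength", "degree_matched_nulls",
    "small_worldness", "subject_graph_metrics",
]


@dataclass
class WeightedGraph:
    nodes: list[str]
    weights: np.ndarray  # symmetric, non-negative, zero diagonal

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.shape != (len(self.nodes), len(self.nodes)):
            raise ValueError("weight matrix shape must match node count")
        if not np.allclose(w, w.T, atol=1e-12):
            raise ValueError("weight matrix must be symmetric")
        if np.any(w < 0):
            raise ValueError("weights must be non-negative")
        np.fill_diagonal(w, 0.0)
        self.weights = w

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return int(np.count_nonzero(np.triu(self.weights, 1)))

    def edge_list(self) -> list[tuple[int, int, float]]:
        i, j = np.nonzero(np.triu(self.weights, 1))
        return [(int(a), int(b), float(self.weights[a, b])) for a, b in zip(i, j)]


def build_graph(plv_rows, node_set: list[str]) -> WeightedGraph:
    """Symmetric PLV weight matrix from a full matrix or tidy pair rows.

    ``plv_rows`` is either an (n, n) matrix over ``node_set``, or a DataFrame
    with ``pair``/``plv`` columns (pair-set mode; unmeasured entries stay 0).
    """
    if not node_set:
        raise ValueError("empty node set")
    n = len(node_set)
    idx = {lab: i for i, lab in enumerate(node_set)}
    if hasattr(plv_rows, "columns"):
        w = np.zeros((n, n))
        for _, row in plv_rows.iterrows():
            a, b = row["pair"].split("-")
            w[idx[a], idx[b]] = w[idx[b], idx[a]] = row["plv"]
        return WeightedGraph(list(node_set), w)
    w = np.asarray(plv_rows, dtype=float)
    if not np.allclose(w, w.T, atol=1e-12):
        raise ValueError("asymmetric PLV matrix")
    return WeightedGraph(list(node_set), w.copy())


def threshold(graph: WeightedGraph, density: float = 0.10) -> WeightedGraph:
    """Keep the floor(density * n(n-1)/2) largest-weight edges, weights preserved.

    Ties at the cutoff are broken by lexicographic node-pair order, so the
    result is deterministic.
    """
    if not 0 < density <= 1:
        raise ValueError("density must be in (0, 1]")
    n = graph.n_nodes
    k = int(np.floor(density * n * (n - 1) / 2))
    if k == 0:
        raise ValueError("density too low: zero edges would remain")
    iu, ju = np.triu_indices(n, 1)
    order = sorted(range(len(iu)),
                   key=lambda e: (-graph.weights[iu[e], ju[e]], int(iu[e]), int(ju[e])))
    keep = order[:k]
    w = np.zeros_like(graph.weights)
    w[iu[keep], ju[keep]] = graph.weights[iu[keep], ju[keep]]
    return WeightedGraph(list(graph.nodes), w + w.T)


def _distance_matrix(weights: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore"):
        lengths = np.where(weights > 0, 1.0 / weights, 0.0)
    return dijkstra(lengths, directed=False)


def global_efficiency(graph: WeightedGraph) -> float:
    """E2: mean of 1/d_ij over the n(n-1) ordered node pairs (disconnected -> 0)."""
    n = graph.n_nodes
    if n < 2:
        raise ValueError("need at least 2 nodes")
    d = _distance_matrix(graph.weights)
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(d) & (d > 0), 1.0 / d, 0.0)
    np.fill_diagonal(inv, 0.0)
    return float(inv.sum() / (n * (n - 1)))


def local_efficiency(graph: WeightedGraph) -> float:
    """E3: mean over nodes of the efficiency of the neighbor-induced subgraph.

    Paths are confined to the subgraph; nodes with fewer than two neighbors
    contribute 0.
    """
    n = graph.n_nodes
    if n < 2:
        raise ValueError("need at least 2 nodes")
    total = 0.0
    for i in range(n):
        nbrs = np.flatnonzero(graph.weights[i] > 0)
        m = len(nbrs)
        if m < 2:
            continue
        sub = graph.weights[np.ix_(nbrs, nbrs)]
        d = _distance_matrix(sub)
        with np.errstate(divide="ignore"):
            inv = np.where(np.isfinite(d) & (d > 0), 1.0 / d, 0.0)
        np.fill_diagonal(inv, 0.0)
        total += inv.sum() / (m * (m - 1))
    return float(total / n)


def _to_nx(graph: WeightedGraph) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(range(graph.n_nodes))
    g.add_weighted_edges_from(graph.edge_list())
    return g


def clustering_and_pathlength(graph: WeightedGraph) -> tuple[float, float]:
    """Weighted clustering coefficient (Onnela, max-weight normalized) and
    characteristic path length (mean distance over connected ordered pairs)."""
    if graph.n_nodes < 3:
        raise ValueError("need at least 3 nodes")
    c = float(nx.average_clustering(_to_nx(graph), weight="weight"))
    d = _distance_matrix(graph.weights)
    off = ~np.eye(graph.n_nodes, dtype=bool)
    finite = np.isfinite(d) & off
    if not finite.any():
        raise ValueError("fully disconnected graph: path length undefined")
    return c, float(d[finite].mean())


def degree_matched_nulls(graph: WeightedGraph, n_random: int = 100,
                         rng: np.random.Generator | int | None = None
                         ) -> tuple[float, float]:
    """Mean (C_rand, L_rand) over Maslov-Sneppen degree-preserving nulls.

    Each null applies 10x edge-count successful double-edge swaps to the
    binary structure, then randomly permutes the observed weights over the
    rewired edge set.
    """
    if graph.n_edges < 2:
        raise ValueError("need at least 2 edges to rewire")
    rng = np.random.default_rng(rng)
    base = _to_nx(graph)
    weights = np.array([w for _, _, w in graph.edge_list()])
    n_swap = 10 * graph.n_edges
    cs, ls = [], []
    for _ in range(n_random):
        g = base.copy()
        try:
            nx.double_edge_swap(g, nswap=n_swap, max_tries=100 * n_swap,
                                seed=int(rng.integers(2 ** 31)))
        except nx.NetworkXAlgorithmError:
            log.warning("degree_matched_nulls: swap budget unreachable; "
                        "null uses fewer than %d swaps", n_swap)
        w = np.zeros_like(graph.weights)
        perm = rng.permutation(len(weights))
        for (a, b), wt in zip(sorted(g.edges()), weights[perm]):
            w[a, b] = w[b, a] = wt
        null = WeightedGraph(list(graph.nodes), w)
        c, l = clustering_and_pathlength(null)
        cs.append(c)
        ls.append(l)
    return float(np.mean(cs)), float(np.mean(ls))


def small_worldness(c: float, l: float, c_rand: float, l_rand: float) -> float:
    """E4: sigma = (C/C_rand) / (L/L_rand)."""
    if c_rand <= 0 or l_rand <= 0:
        raise ValueError("null means must be positive")
    return (c / c_rand) / (l / l_rand)


def subject_graph_metrics(graph: WeightedGraph, density: float = 0.10,
                          n_random: int = 100,
                          rng: np.random.Generator | int | None = None) -> dict:
    """Threshold a subject's PLV graph and compute the full metric panel."""
    thr = threshold(graph, density)
    ge = global_efficiency(thr)
    le = local_efficiency(thr)
    c, l = clustering_and_pathlength(thr)
    c_rand, l_rand = degree_matched_nulls(thr, n_random=n_random, rng=rng)
    return {
        "GE": ge, "LE": le, "C": c, "L": l,
        "C_rand": c_rand, "L_rand": l_rand,
        "sigma": small_worldness(c, l, c_rand, l_rand),
        "density": density, "n_edges": thr.n_edges,
    }
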