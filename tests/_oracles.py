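"""Independent brute-force oracles used to cross-check the package's metrics
and trajectory logic. Deliberately naive: exhaustive enumeration and dense
linear algebra, no shared code with the implementation under test."""

from __future__ import annotations

import itertools

import networkx as nx
import numpy as np


def brute_clustering(g: nx.Graph, node) -> float:
    """2 e_i / (k_i (k_i - 1)) by exhaustive neighbour-pair enumeration."""
    nbrs = list(g.neighbors(node))
    k = len(nbrs)
    if k < 2:
        return 0.0
    e = sum(1 for u, v in itertools.combinations(nbrs, 2) if g.has_edge(u, v))
    return 2.0 * e / (k * (k - 1))


def brute_pagerank(g, d: float = 0.85, weighted: bool = True) -> dict:
    """Exact damped PageRank by dense linear solve; dangling rows spread
    their mass uniformly."""
    nodes = sorted(g.nodes)
    n = len(nodes)
    idx = {u: i for i, u in enumerate(nodes)}
    W = np.zeros((n, n))
    for u, v, data in g.edges(data=True):
        w = float(data.get("weight", 1.0)) if weighted else 1.0
        W[idx[u], idx[v]] += w
        if not g.is_directed():
            W[idx[v], idx[u]] += w
    P = np.zeros((n, n))
    for i in range(n):
        s = W[i].sum()
        P[i] = W[i] / s if s > 0 else 1.0 / n
    x = np.linalg.solve(np.eye(n) - d * P.T, np.full(n, (1.0 - d) / n))
    return dict(zip(nodes, x))


def brute_density(g) -> float:
    """Adjacency-matrix-sum definition: sum_ij m_ij / (n (n - 1))."""
    nodes = sorted(g.nodes)
    n = len(nodes)
    if n < 2:
        return 0.0
    m = nx.to_numpy_array(g, nodelist=nodes, weight=None)
    return float(m.sum()) / (n * (n - 1))


def brute_diameter(g: nx.Graph) -> int:
    """Max pairwise BFS distance on the largest connected component."""
    comps = list(nx.connected_components(g))
    largest = max(comps, key=len)
    if len(largest) < 2:
        return 0
    best = 0
    for u in largest:
        lengths = nx.single_source_shortest_path_length(g.subgraph(largest), u)
        best = max(best, max(lengths.values()))
    return best


def brute_centralization(g: nx.Graph) -> float:
    n = g.number_of_nodes()
    if n < 3:
        return 0.0
    degs = [g.degree(u) for u in g.nodes]
    return sum(max(degs) - k for k in degs) / ((n - 1) * (n - 2)) * 100.0


def brute_trajectory_arcs(g: nx.DiGraph, focal, min_or: float, depth: int):
    """All arcs lying on some directed walk of <= depth arcs out of focal,
    restricted to arcs with OR >= min_or, by exhaustive walk enumeration."""
    strong = [(u, v) for u, v, d in g.edges(data=True) if d.get("odds_ratio", 0) >= min_or]
    adj: dict = {}
    for u, v in strong:
        adj.setdefault(u, []).append(v)
    arcs = set()

    def walk(node, used):
        if used == depth:
            return
        for nxt in adj.get(node, []):
            arcs.add((node, nxt))
            walk(nxt, used + 1)

    walk(focal, 0)
    return arcs
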