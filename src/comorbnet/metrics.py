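"""Node attributes and whole-network statistics.

Per node: degree (in/out for directed networks), the local clustering
coefficient 2 e_i / (k_i (k_i - 1)) with e_i the number of edges among node
i's neighbours (0 when k_i < 2), and damped PageRank

    PR(g) = (1 - d) / N + d * sum_{u -> g} PR(u) / N_out(u),   d = 0.85,

computed by power iteration. Undirected edges are treated as bi-directional;
in the weighted variant a node's PageRank mass is split over its out-arcs
proportionally to the arc odds-ratio weights; dangling nodes (no out-arcs)
shed their mass uniformly over the whole network, so the scores always sum
to 1.

Per network: node/edge counts, average clustering (the mean of per-node
coefficients, not the triangle/transitivity ratio), unweighted diameter
(largest connected component of the undirected view, flagged when the
network is disconnected), density sum_ij m_ij / (n (n - 1)) of the adjacency
matrix, and Freeman degree centralization sum_i (k_max - k_i) normalised by
(n - 1)(n - 2) and expressed as a percentage: 0 for a complete (or any
regular) graph, 100 for a star.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .errors import ConvergenceError
from .network import MorbidityNetwork


def _graph(network) -> nx.Graph | nx.DiGraph:
    return network.graph if isinstance(network, MorbidityNetwork) else network


def _undirected_view(g) -> nx.Graph:
    """Simple undirected unweighted view (double arcs collapse to one edge)."""
    return nx.Graph(g)


@dataclass
class NetworkSummary:
    n_nodes: int
    n_edges: int
    avg_clustering: float
    diameter: int
    disconnected: bool
    density: float
    centralization: float  # percentage in [0, 100]


def clustering_coefficient(network, node=None):
    """Local clustering coefficient(s) on the undirected view of the network;
    a dict over all nodes, or a single value when ``node`` is given."""
    u = _undirected_view(_graph(network))
    if node is not None:
        return nx.clustering(u, node)
    return nx.clustering(u)


def degree_metrics(network) -> pd.DataFrame:
    """Per-node degree table; directed networks get in/out degrees and their
    sum, with undefined-direction double arcs counted in both."""
    g = _graph(network)
    nodes = sorted(g.nodes)
    if g.is_directed():
        return pd.DataFrame(
            {
                "code": nodes,
                "in_degree": [g.in_degree(n) for n in nodes],
                "out_degree": [g.out_degree(n) for n in nodes],
                "degree": [g.in_degree(n) + g.out_degree(n) for n in nodes],
            }
        )
    return pd.DataFrame({"code": nodes, "degree": [g.degree(n) for n in nodes]})


def pagerank(network, d: float = 0.85, weighted: bool = True,
             tol: float = 1e-12, max_iter: int = 1000) -> dict[str, float]:
    """Damped PageRank by power iteration (see module docstring).

    ``tol`` bounds the L1 change between successive iterates; exceeding
    ``max_iter`` raises ConvergenceError carrying the last residual.
    """
    g = _graph(network)
    nodes = sorted(g.nodes)
    n = len(nodes)
    if n == 0:
        raise ConvergenceError("pagerank of an empty network is undefined")
    idx = {node: i for i, node in enumerate(nodes)}
    W = np.zeros((n, n))
    for u, v, data in g.edges(data=True):
        w = float(data.get("weight", 1.0)) if weighted else 1.0
        W[idx[u], idx[v]] += w
        if not g.is_directed():
            W[idx[v], idx[u]] += w
    out_sum = W.sum(axis=1)
    dangling = out_sum == 0
    P = np.divide(W, out_sum[:, None], out=np.zeros_like(W), where=~dangling[:, None])
    x = np.full(n, 1.0 / n)
    for _ in range(max_iter):
        x_new = (1.0 - d) / n + d * (P.T @ x + x[dangling].sum() / n)
        err = float(np.abs(x_new - x).sum())
        x = x_new
        if err < tol:
            return dict(zip(nodes, x))
    raise ConvergenceError(
        f"pagerank did not converge in {max_iter} iterations (residual {err:.3e})",
        residual=err,
    )


def node_attributes(network, d: float = 0.85, weighted: bool = True) -> pd.DataFrame:
    """Degree, clustering coefficient and PageRank for every node."""
    deg = degree_metrics(network)
    clus = clustering_coefficient(network)
    pr = pagerank(network, d=d, weighted=weighted)
    deg["clustering_coefficient"] = deg["code"].map(clus)
    deg["pagerank"] = deg["code"].map(pr)
    return deg


def degree_centralization(g: nx.Graph) -> float:
    """Freeman degree centralization of an undirected simple graph, as a
    percentage; 0 by convention when n < 3 (no star/complete contrast)."""
    n = g.number_of_nodes()
    if n < 3:
        return 0.0
    degrees = np.array([d for _, d in g.degree()])
    return float(degrees.max() * n - degrees.sum()) / ((n - 1) * (n - 2)) * 100.0


def summarize(network) -> NetworkSummary:
    """Whole-network statistics (see module docstring for conventions)."""
    g = _graph(network)
    n = g.number_of_nodes()
    m = g.number_of_edges()
    u = _undirected_view(g)
    if n == 0:
        return NetworkSummary(0, 0, float("nan"), 0, False, 0.0, 0.0)
    clus = nx.clustering(u)
    avg_clustering = float(np.mean(list(clus.values())))
    components = list(nx.connected_components(u))
    disconnected = len(components) > 1
    largest = max(components, key=len)
    diameter = nx.diameter(u.subgraph(largest)) if len(largest) > 1 else 0
    density = float(nx.density(g)) if n > 1 else 0.0
    return NetworkSummary(
        n_nodes=n,
        n_edges=m,
        avg_clustering=avg_clustering,
        diameter=int(diameter),
        disconnected=disconnected,
        density=density,
        centralization=degree_centralization(u),
    )


def summary_to_frame(summary: NetworkSummary) -> pd.DataFrame:
    return pd.DataFrame([summary.__dict__])
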