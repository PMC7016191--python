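"""Comorbidity network assembly: undirected and directed graphs from
filtered edges, focal-condition subnets, and disease trajectories.

Networks carry the odds ratio as the edge weight. In the directed network a
pair with a defined temporal direction contributes exactly one arc, and a
pair with undefined direction contributes two (one each way, the familiar
double arrow) — which is why directed networks report more edges than the
undirected network at the same OR threshold. Nodes with no passing edge are
omitted, so node counts equal incident nodes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from .association import PairAssociation, associations_to_frame
from .errors import InputError
from .temporal import LABEL_A_TO_B, LABEL_B_TO_A, LABEL_UNDEFINED


@dataclass
class MorbidityNetwork:
    """A networkx graph plus provenance of the filters that produced it."""

    graph: nx.Graph | nx.DiGraph
    directed: bool
    provenance: dict = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        """Edge count; for directed networks this counts arcs, so undefined
        pairs are counted twice."""
        return self.graph.number_of_edges()


@dataclass
class Trajectory:
    """Disease trajectory around a focal condition: one-step predecessors and
    directed walks up to ``depth`` arcs downstream, all with OR >= min_or.

    ``immediate_predecessors`` counts, for every condition reached downstream,
    the distinct conditions with a trajectory arc directly into it — the
    "number of different previous conditions" a disease can be reached from.
    """

    focal: str
    min_or: float
    depth: int
    predecessor_arcs: list[tuple[str, str, float]]
    successor_arcs: list[tuple[str, str, float]]
    distances: dict[str, int]
    immediate_predecessors: dict[str, int]


def _edges_frame(edges) -> pd.DataFrame:
    if isinstance(edges, pd.DataFrame):
        df = edges.copy()
    elif len(edges) and isinstance(edges[0], PairAssociation):
        df = associations_to_frame(list(edges))
    else:
        df = pd.DataFrame(list(edges), columns=["code_a", "code_b", "odds_ratio"])
    for col in ("code_a", "code_b", "odds_ratio"):
        if col not in df.columns:
            if df.empty:
                df[col] = pd.Series(dtype=object)
            else:
                raise InputError(f"edge rows lack required column {col!r}")
    if "p_value" not in df.columns:
        df["p_value"] = math.nan
    a = df[["code_a", "code_b"]].min(axis=1)
    b = df[["code_a", "code_b"]].max(axis=1)
    df["code_a"], df["code_b"] = a, b
    if (df["code_a"] == df["code_b"]).any():
        raise InputError("self-loop edge rows are not allowed")
    return df


def build_undirected(edges, labels: dict[str, str] | None = None,
                     provenance: dict | None = None) -> MorbidityNetwork:
    """Simple weighted graph from filtered pair associations; weight = OR.
    Duplicate pair rows with conflicting ORs are an error."""
    df = _edges_frame(edges)
    dup = df.groupby(["code_a", "code_b"])["odds_ratio"].nunique()
    if (dup > 1).any():
        raise InputError(f"conflicting duplicate edges: {dup[dup > 1].index.tolist()}")
    df = df.drop_duplicates(subset=["code_a", "code_b"])
    g = nx.Graph()
    for row in df.itertuples(index=False):
        g.add_edge(row.code_a, row.code_b, weight=float(row.odds_ratio),
                   odds_ratio=float(row.odds_ratio), p_value=float(row.p_value))
    _apply_labels(g, labels)
    return MorbidityNetwork(g, directed=False, provenance=provenance or {})


def build_directed(edges, directions, labels: dict[str, str] | None = None,
                   provenance: dict | None = None) -> MorbidityNetwork:
    """Directed network: a pair labelled a_to_b/b_to_a contributes one arc,
    an undefined pair two arcs; arc weight = the pair OR.

    ``directions`` maps canonical pairs to labels — either a dict or a frame
    with columns (code_a, code_b, label). Every edge needs a label.
    """
    df = _edges_frame(edges)
    if isinstance(directions, pd.DataFrame):
        dmap = {
            (min(r.code_a, r.code_b), max(r.code_a, r.code_b)): r.label
            for r in directions.itertuples(index=False)
        }
    else:
        dmap = {(min(a, b), max(a, b)): lab for (a, b), lab in directions.items()}
    g = nx.DiGraph()
    for row in df.itertuples(index=False):
        key = (row.code_a, row.code_b)
        if key not in dmap:
            raise InputError(f"edge {key} has no direction label")
        label = dmap[key]
        attrs = dict(weight=float(row.odds_ratio), odds_ratio=float(row.odds_ratio),
                     p_value=float(row.p_value), direction=label)
        if label == LABEL_A_TO_B:
            g.add_edge(row.code_a, row.code_b, **attrs)
        elif label == LABEL_B_TO_A:
            g.add_edge(row.code_b, row.code_a, **attrs)
        elif label == LABEL_UNDEFINED:
            g.add_edge(row.code_a, row.code_b, **attrs)
            g.add_edge(row.code_b, row.code_a, **attrs)
        else:
            raise InputError(f"unknown direction label {label!r} for {key}")
    _apply_labels(g, labels)
    return MorbidityNetwork(g, directed=True, provenance=provenance or {})


def _apply_labels(g, labels: dict[str, str] | None) -> None:
    if labels:
        nx.set_node_attributes(g, {n: labels[n] for n in g.nodes if n in labels}, "label")


def fixture_edge_inputs(fixture: pd.DataFrame, min_or: float = 0.0):
    """Convert a (from, to, odds_ratio, direction) edge list — the packaged
    worked-example table — into the (edges, directions, labels) triple the
    builders consume, keeping rows with OR >= min_or."""
    rows = fixture[fixture["odds_ratio"] >= min_or]
    edges, directions, labels = [], {}, {}
    cols = ["from", "to", "label", "odds_ratio", "direction"]
    for src, dst, lab, or_value, dirn in rows[cols].itertuples(index=False, name=None):
        a, b = sorted((src, dst))
        edges.append((a, b, or_value))
        if dirn == "undefined":
            directions[(a, b)] = LABEL_UNDEFINED
        else:
            directions[(a, b)] = LABEL_A_TO_B if src == a else LABEL_B_TO_A
        labels[dst if src == "T90" else src] = lab
    return edges, directions, labels


def extract_subnet(network: MorbidityNetwork, focal: str) -> MorbidityNetwork:
    """Closed-neighbourhood induced subgraph of the focal condition: the
    focal node, its neighbours (either arc direction), and all edges among
    them — the 'zoomed' subnet of one chronic condition."""
    g = network.graph
    if focal not in g:
        raise InputError(f"focal condition {focal!r} is not in the network")
    if network.directed:
        nbrs = set(g.predecessors(focal)) | set(g.successors(focal))
    else:
        nbrs = set(g.neighbors(focal))
    sub = g.subgraph(nbrs | {focal}).copy()
    prov = dict(network.provenance, focal=focal)
    return MorbidityNetwork(sub, directed=network.directed, provenance=prov)


def build_trajectory(network: MorbidityNetwork, focal: str, min_or: float = 1.5,
                     depth: int = 3) -> Trajectory:
    """Trajectory of a focal condition over arcs with OR >= min_or:
    predecessors are the arcs one step into the focal node; successors are
    every arc lying on a directed walk of at most ``depth`` arcs out of it
    (undefined-direction pairs are two arcs, hence traversable both ways;
    cycles are cut by the depth bound)."""
    if not network.directed:
        raise InputError("trajectories require a directed network")
    g = network.graph
    strong = nx.DiGraph()
    strong.add_nodes_from(g.nodes)
    strong.add_edges_from(
        (u, v, d) for u, v, d in g.edges(data=True) if d.get("odds_ratio", 0.0) >= min_or
    )
    predecessor_arcs = (
        [(u, focal, strong[u][focal]["odds_ratio"]) for u in sorted(strong.predecessors(focal))]
        if focal in strong else []
    )
    successor_arcs: list[tuple[str, str, float]] = []
    distances: dict[str, int] = {}
    if focal in strong:
        dist = nx.single_source_shortest_path_length(strong, focal, cutoff=depth)
        distances = {n: d for n, d in dist.items() if n != focal}
        for u, v, d in strong.edges(data=True):
            if dist.get(u, depth + 1) <= depth - 1:
                successor_arcs.append((u, v, d["odds_ratio"]))
    successor_arcs.sort()
    preds: dict[str, set[str]] = {}
    for u, v, _ in successor_arcs:
        preds.setdefault(v, set()).add(u)
    return Trajectory(
        focal=focal,
        min_or=min_or,
        depth=depth,
        predecessor_arcs=predecessor_arcs,
        successor_arcs=successor_arcs,
        distances=distances,
        immediate_predecessors={v: len(s) for v, s in sorted(preds.items())},
    )
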