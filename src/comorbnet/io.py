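"""Delimited-text I/O, packaged fixtures and graph serialisation.

All tabular inputs and outputs are tab-separated text with ISO-8601 dates.
Graphs are written as GraphML and as a small JSON dialect
(``{"directed", "provenance", "nodes": [...], "edges": [...]}``) that
round-trips through :func:`read_graph_json` without loss.
"""

from __future__ import annotations

import hashlib
import json
from importlib import resources
from pathlib import Path

import networkx as nx
import pandas as pd

from .errors import FixtureIntegrityError, InputError
from .network import MorbidityNetwork

_DATE_COLUMNS = {"birth_date", "end_date", "diagnosis_date", "resolution_date"}

#: sha256 of the packaged worked-example edge list (37 printed rows).
TABLE2_SHA256 = "9df2fdd462ea0edcb5450a1bf4e6374a58b59ba1204e04a2eed9e31014e316e1"
TABLE2_ROWS = 37


def _read_tsv(path, required: tuple[str, ...]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", dtype={"patient_id": str, "code": str})
    except (OSError, pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise InputError(f"cannot read table {path}: {exc}") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise InputError(f"{path}: missing required columns {missing}")
    for col in _DATE_COLUMNS & set(df.columns):
        df[col] = pd.to_datetime(df[col], format="ISO8601", errors="raise")
    return df


def read_patients(path) -> pd.DataFrame:
    return _read_tsv(path, required=("patient_id", "sex", "birth_date"))


def read_diagnoses(path) -> pd.DataFrame:
    return _read_tsv(path, required=("patient_id", "code", "diagnosis_date"))


def write_table(df: pd.DataFrame, path) -> None:
    out = df.copy()
    for col in _DATE_COLUMNS & set(out.columns):
        out[col] = pd.to_datetime(out[col]).dt.strftime("%Y-%m-%d")
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    out.to_csv(path, sep="\t", index=False)


def read_catalog_tables(conditions_path=None, mapping_path=None):
    """Read (conditions, mapping) tables; defaults to the packaged
    illustrative catalog (~40 ICPC-2 codes) and ICD-10 crosswalk sample."""
    base = resources.files("comorbnet") / "data"
    cpath = conditions_path or base / "condition_catalog.tsv"
    conditions = _read_tsv(cpath, required=("code", "label", "system", "chronic"))
    mpath = mapping_path or base / "icd10_icpc2_mapping.tsv"
    mapping = _read_tsv(mpath, required=("source_system", "source_code",
                                         "target_system", "target_code"))
    return conditions, mapping


def load_table2_fixture() -> pd.DataFrame:
    """The packaged worked-example directed edge list around T90 (type 2
    diabetes): 37 rows of (from, to, label, odds_ratio, direction) with
    direction 'directed' or 'undefined'. Verified against a checksum."""
    res = resources.files("comorbnet") / "data" / "t2dm_directed_edges.tsv"
    raw = res.read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != TABLE2_SHA256:
        raise FixtureIntegrityError(
            f"fixture checksum mismatch: expected {TABLE2_SHA256}, got {digest}"
        )
    df = pd.read_csv(res.open("r"), sep="\t")
    if len(df) != TABLE2_ROWS:
        raise FixtureIntegrityError(f"fixture has {len(df)} rows, expected {TABLE2_ROWS}")
    return df


def write_graphml(network: MorbidityNetwork, path) -> None:
    g = network.graph.copy()
    g.graph["directed"] = network.directed
    g.graph["provenance"] = json.dumps(network.provenance, default=str, sort_keys=True)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    nx.write_graphml(g, path)


def write_graph_json(network: MorbidityNetwork, path) -> None:
    payload = {
        "directed": network.directed,
        "provenance": network.provenance,
        "nodes": [
            {"id": n, **{k: v for k, v in d.items()}}
            for n, d in sorted(network.graph.nodes(data=True))
        ],
        "edges": [
            {"source": u, "target": v, **{k: v2 for k, v2 in d.items()}}
            for u, v, d in sorted(network.graph.edges(data=True))
        ],
    }
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True, default=str)


def read_graph_json(path) -> MorbidityNetwork:
    with open(path) as fh:
        payload = json.load(fh)
    g = nx.DiGraph() if payload["directed"] else nx.Graph()
    for node in payload["nodes"]:
        attrs = {k: v for k, v in node.items() if k != "id"}
        g.add_node(node["id"], **attrs)
    for edge in payload["edges"]:
        attrs = {k: v for k, v in edge.items() if k not in ("source", "target")}
        g.add_edge(edge["source"], edge["target"], **attrs)
    return MorbidityNetwork(g, directed=payload["directed"],
                            provenance=payload.get("provenance", {}))


def write_edge_list(network: MorbidityNetwork, path) -> None:
    rows = [
        {"code_a": u, "code_b": v,
         "odds_ratio": d.get("odds_ratio"), "p_value": d.get("p_value"),
         **({"direction": d["direction"]} if "direction" in d else {})}
        for u, v, d in sorted(network.graph.edges(data=True))
    ]
    write_table(pd.DataFrame(rows), path)
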