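"""End-to-end pipeline: cohort -> adjusted pair ORs -> temporal direction ->
networks -> metrics -> focal subnets and trajectories.

The pipeline is a pure function of its configuration and input tables; every
output carries the configuration as provenance, and a structured log line per
stage records counts (patients kept, pairs fitted, edges kept, arcs
directed/undefined). Stratified networks (by sex or age group) and the
complete-records-only sensitivity variant are cohort-level filters reusing
the same stages, not separate code paths.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path

import pandas as pd
import yaml

from . import io as cio
from .association import (
    EdgeFilter,
    associations_to_frame,
    build_presence_matrix,
    estimate_all_pairs,
    filter_edges,
)
from .cohort import (
    Cohort,
    ConditionCatalog,
    filter_chronic,
    map_codes,
    select_multimorbid,
)
from .errors import ConfigError
from .metrics import node_attributes, summarize, summary_to_frame
from .network import MorbidityNetwork, build_directed, build_undirected, build_trajectory, extract_subnet
from .temporal import direction_table

logger = logging.getLogger("comorbnet")


@dataclass
class PipelineConfig:
    """Everything the pipeline needs beyond the input tables.

    Threshold ranges mirror the interactive tool the analysis was designed
    for: risk-mode minimum OR between 1.2 and 2.0, protective-mode maximum
    between 0.8 and 0.5, direction thresholds 0.40/0.60 (or the stricter
    0.20/0.80 sensitivity variant).
    """

    period: tuple[date, date] = (date(2006, 1, 1), date(2017, 12, 31))
    min_or: float = 1.2
    max_or: float = 0.8
    max_p: float = 1e-5
    min_patients: int = 1000
    mode: str = "risk"
    direction_low: float = 0.40
    direction_high: float = 0.60
    trajectory_min_or: float = 1.5
    trajectory_depth: int = 3
    coexistence: str = "strict"
    complete_records_only: bool = False
    sex: str | None = None  # 'M' or 'F' restricts the cohort
    age_min: float | None = None
    age_max: float | None = None
    outcome: str = "less_prevalent"
    age_groups: bool = False
    focal: list[str] = field(default_factory=list)
    output_dir: str | None = None
    seed: int = 0

    def edge_filter(self) -> EdgeFilter:
        return EdgeFilter(min_or=self.min_or, max_or=self.max_or, max_p=self.max_p,
                          min_patients=self.min_patients, mode=self.mode)

    def validate(self) -> None:
        self.edge_filter()
        if not (0 < self.direction_low < self.direction_high < 1):
            raise ConfigError("direction thresholds must satisfy 0 < low < high < 1")
        if self.trajectory_depth < 1:
            raise ConfigError("trajectory depth must be >= 1")
        if self.sex not in (None, "M", "F"):
            raise ConfigError("sex stratum must be 'M', 'F' or unset")
        if self.coexistence not in ("strict", "lenient"):
            raise ConfigError(f"unknown coexistence mode {self.coexistence!r}")

    def provenance(self) -> dict:
        d = dataclasses.asdict(self)
        d["period"] = [p.isoformat() for p in self.period]
        return d

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "period" in raw:
            raw["period"] = tuple(
                p if isinstance(p, date) else date.fromisoformat(str(p)) for p in raw["period"]
            )
        cfg = cls(**raw)
        cfg.validate()
        return cfg


@dataclass
class PipelineResult:
    config: PipelineConfig
    cohort: Cohort
    associations: pd.DataFrame
    directions: pd.DataFrame
    undirected: MorbidityNetwork
    directed: MorbidityNetwork
    node_attributes_undirected: pd.DataFrame
    node_attributes_directed: pd.DataFrame
    summary_undirected: pd.DataFrame
    summary_directed: pd.DataFrame
    subnets: dict
    trajectories: dict


def _restrict_cohort(cohort: Cohort, config: PipelineConfig) -> Cohort:
    pats = cohort.patients
    if config.complete_records_only:
        pats = pats[pats["covariates_complete"]]
    if config.sex is not None:
        pats = pats[pats["sex"] == config.sex]
    if config.age_min is not None:
        pats = pats[pats["analysis_age"] >= config.age_min]
    if config.age_max is not None:
        pats = pats[pats["analysis_age"] < config.age_max]
    if len(pats) < len(cohort.patients):
        ev = cohort.events[cohort.events["patient_id"].isin(set(pats["patient_id"]))]
        logger.info("stratify: %d of %d patients kept", len(pats), len(cohort.patients))
        return Cohort(pats.reset_index(drop=True), ev.reset_index(drop=True), cohort.period)
    return cohort


def run_pipeline(
    config: PipelineConfig,
    patients: pd.DataFrame,
    diagnoses: pd.DataFrame,
    catalog: ConditionCatalog | None = None,
) -> PipelineResult:
    """Run every stage on raw patient/diagnosis tables and return all outputs;
    writes them under ``config.output_dir`` when set."""
    config.validate()
    if catalog is None:
        conditions, mapping = cio.read_catalog_tables()
        catalog = ConditionCatalog(conditions, mapping)
    labels = catalog.labels()

    mapped = map_codes(diagnoses, catalog)
    chronic = filter_chronic(mapped.events, catalog)
    cohort = select_multimorbid(patients, chronic, config.period,
                                coexistence=config.coexistence)
    cohort = _restrict_cohort(cohort, config)

    presence = build_presence_matrix(cohort)
    filt = config.edge_filter()
    associations = estimate_all_pairs(presence, filt, outcome=config.outcome,
                                      age_groups=config.age_groups)
    edges = filter_edges(associations, filt)
    assoc_df = associations_to_frame(associations)

    pairs = [(e.code_a, e.code_b) for e in edges]
    directions = direction_table(cohort, pairs, low=config.direction_low,
                                 high=config.direction_high)
    n_directed = int((directions["label"] != "undefined").sum())
    logger.info("directions: %d directed, %d undefined of %d edges",
                n_directed, len(directions) - n_directed, len(directions))

    prov = config.provenance()
    undirected = build_undirected(edges, labels=labels, provenance=prov)
    directed = build_directed(edges, directions, labels=labels, provenance=prov)

    attrs_u = node_attributes(undirected) if undirected.n_nodes else pd.DataFrame()
    attrs_d = node_attributes(directed) if directed.n_nodes else pd.DataFrame()
    summ_u = summary_to_frame(summarize(undirected))
    summ_d = summary_to_frame(summarize(directed))

    subnets, trajectories = {}, {}
    for code in config.focal:
        if code in undirected.graph:
            subnets[code] = extract_subnet(undirected, code)
        if code in directed.graph:
            trajectories[code] = build_trajectory(
                directed, code, min_or=config.trajectory_min_or,
                depth=config.trajectory_depth,
            )

    result = PipelineResult(
        config=config, cohort=cohort, associations=assoc_df, directions=directions,
        undirected=undirected, directed=directed,
        node_attributes_undirected=attrs_u, node_attributes_directed=attrs_d,
        summary_undirected=summ_u, summary_directed=summ_d,
        subnets=subnets, trajectories=trajectories,
    )
    if config.output_dir:
        _write_outputs(result, Path(config.output_dir))
    return result


def _write_outputs(result: PipelineResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    cio.write_table(result.associations, outdir / "pair_associations.tsv")
    cio.write_table(result.directions, outdir / "edge_directions.tsv")
    cio.write_table(result.node_attributes_undirected, outdir / "node_attributes_undirected.tsv")
    cio.write_table(result.node_attributes_directed, outdir / "node_attributes_directed.tsv")
    cio.write_table(result.summary_undirected, outdir / "network_summary_undirected.tsv")
    cio.write_table(result.summary_directed, outdir / "network_summary_directed.tsv")
    for name, net in (("undirected", result.undirected), ("directed", result.directed)):
        cio.write_graphml(net, outdir / f"network_{name}.graphml")
        cio.write_graph_json(net, outdir / f"network_{name}.json")
        cio.write_edge_list(net, outdir / f"network_{name}_edges.tsv")
    for code, sub in result.subnets.items():
        safe = code.replace("/", "_")
        cio.write_graph_json(sub, outdir / f"subnet_{safe}.json")
    for code, traj in result.trajectories.items():
        safe = code.replace("/", "_")
        rows = [
            {"role": "predecessor", "source": u, "target": v, "odds_ratio": o}
            for u, v, o in traj.predecessor_arcs
        ] + [
            {"role": "successor", "source": u, "target": v, "odds_ratio": o}
            for u, v, o in traj.successor_arcs
        ]
        cio.write_table(pd.DataFrame(rows, columns=["role", "source", "target", "odds_ratio"]),
                        outdir / f"trajectory_{safe}.tsv")


AGE_GROUP_BINS = [18, 45, 65, 80]


def _age_group(age: pd.Series) -> pd.Series:
    import numpy as np

    bins = [-np.inf] + AGE_GROUP_BINS[1:] + [np.inf]
    labels = ["18-44", "45-64", "65-79", "80+"]
    return pd.cut(age, bins=bins, labels=labels, right=False).astype(str)


def descriptive_summary(
    cohort: Cohort,
    strata: tuple[str, ...] = ("sex", "age_group"),
    all_patients: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Descriptive statistics of the analysis cohort by sex/age-group strata:
    patient counts, mean analysis age, per-condition prevalence within the
    stratum, and — when the full (pre-selection) patient table is supplied —
    the multimorbidity prevalence of each stratum. With no strata, a single
    overall row."""
    pats = cohort.patients.copy()
    pats["age_group"] = _age_group(pats["analysis_age"])
    for s in strata:
        if s not in ("sex", "age_group"):
            raise ConfigError(f"unknown stratum {s!r}")
    keys = list(strata) if strata else []
    presence = build_presence_matrix(cohort)
    codes = [c for c in presence.columns if c not in ("age", "sex")]
    merged = pats.set_index("patient_id").join(presence[codes])

    def one(group: pd.DataFrame) -> dict:
        row = {"n": len(group), "mean_age": float(group["analysis_age"].mean()) if len(group) else float("nan")}
        for c in codes:
            row[f"prev_{c}"] = float(group[c].mean()) if len(group) else 0.0
        return row

    if keys:
        groups = merged.groupby(keys, observed=False)
        rows = []
        for key, group in groups:
            key = key if isinstance(key, tuple) else (key,)
            rows.append({**dict(zip(keys, key)), **one(group)})
        out = pd.DataFrame(rows)
    else:
        out = pd.DataFrame([{"stratum": "all", **one(merged)}])

    if all_patients is not None:
        denom = all_patients.copy()
        start, end = pd.Timestamp(cohort.period[0]), pd.Timestamp(cohort.period[1])
        midpoint = start + (end - start) / 2
        denom["analysis_age"] = (midpoint - denom["birth_date"]).dt.days / 365.25
        denom["age_group"] = _age_group(denom["analysis_age"])
        if keys:
            totals = denom.groupby(keys, observed=False).size()
            out = out.set_index(keys)
            out["n_population"] = totals
            out["multimorbidity_prevalence"] = out["n"] / out["n_population"]
            out = out.reset_index()
        else:
            out["n_population"] = len(denom)
            out["multimorbidity_prevalence"] = out["n"] / len(denom)
    return out
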