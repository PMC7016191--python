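"""Cohort construction: code mapping, chronicity filter, multimorbidity
selection, per-patient analysis age and censoring at death/transfer.

The analysis cohort contains adults with at least two coexistent chronic
conditions active at some time within the study period. "Coexistent" is read
strictly by default: at least one pair of chronic conditions must have
overlapping activity intervals inside the period (an activity interval runs
from diagnosis to resolution, or indefinitely when unresolved, truncated at
death/transfer). A lenient mode — both conditions active at some point in the
period, not necessarily simultaneously — is available via ``coexistence``.

A patient's analysis age is the mean of their ages at the first and last
in-period diagnoses, or their age at the period midpoint if no diagnosis was
made within the period. Ages use exact day counts / 365.25.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import date

import numpy as np
import pandas as pd

from .errors import ConfigError, InputError

logger = logging.getLogger("comorbnet")

DAYS_PER_YEAR = 365.25
COVARIATE_COLUMNS = ("tobacco", "alcohol", "weight", "height")

# sentinel for "still active" (open activity interval)
_FAR_FUTURE = pd.Timestamp("2262-01-01")


@dataclass
class ConditionCatalog:
    """Condition codes with labels and chronicity flags, plus optional
    cross-classification mapping rows (source code -> target code)."""

    conditions: pd.DataFrame  # columns: code, label, system, chronic
    mapping: pd.DataFrame | None = None  # columns: source_system, source_code, target_system, target_code [, priority]

    def __post_init__(self) -> None:
        dup = self.conditions.duplicated(subset=["system", "code"])
        if dup.any():
            raise InputError(f"duplicate catalog codes: {self.conditions.loc[dup, 'code'].tolist()}")
        if self.mapping is not None:
            known = set(self.conditions["code"])
            unknown = set(self.mapping["target_code"]) - known
            if unknown:
                raise InputError(f"mapping targets absent from catalog: {sorted(unknown)}")

    @property
    def chronic_codes(self) -> set[str]:
        c = self.conditions
        return set(c.loc[c["chronic"].astype(int) == 1, "code"])

    def labels(self) -> dict[str, str]:
        return dict(zip(self.conditions["code"], self.conditions["label"]))


@dataclass
class MapResult:
    events: pd.DataFrame
    n_dropped: int
    dropped_codes: dict[str, int] = field(default_factory=dict)


@dataclass
class Cohort:
    """Selected patients (with ``analysis_age``) and their chronic diagnosis
    events active within the study period."""

    patients: pd.DataFrame
    events: pd.DataFrame
    period: tuple[date, date]

    @property
    def size(self) -> int:
        return len(self.patients)

    def condition_counts(self) -> pd.Series:
        return self.events.groupby("code")["patient_id"].nunique().sort_index()


def map_codes(events: pd.DataFrame, catalog: ConditionCatalog) -> MapResult:
    """Re-code events through the catalog's mapping table.

    Codes already in the catalog's target system pass through unchanged;
    mappable codes are re-coded; anything else is dropped and counted.
    One-to-many mapping rows require a ``priority`` column (lowest wins),
    otherwise they are an error.
    """
    if catalog.mapping is None or catalog.mapping.empty:
        return MapResult(events.copy(), 0, {})
    mapping = catalog.mapping
    per_source = mapping.groupby("source_code")["target_code"].nunique()
    ambiguous = per_source[per_source > 1].index
    if len(ambiguous):
        if "priority" not in mapping.columns:
            raise InputError(
                f"ambiguous one-to-many mapping without priority for: {sorted(ambiguous)}"
            )
        mapping = mapping.sort_values("priority", kind="mergesort").drop_duplicates(
            "source_code", keep="first"
        )
    lookup = dict(zip(mapping["source_code"], mapping["target_code"]))
    native = set(catalog.conditions["code"])
    out = events.copy()
    mapped = out["code"].map(lookup)
    keep_native = out["code"].isin(native)
    out["code"] = mapped.where(mapped.notna(), out["code"])
    resolved = mapped.notna() | keep_native
    dropped = out.loc[~resolved, "code"].value_counts().to_dict()
    n_dropped = int((~resolved).sum())
    if n_dropped:
        logger.info("map_codes: dropped %d unmapped events (%s)", n_dropped, dropped)
    return MapResult(out.loc[resolved].reset_index(drop=True), n_dropped, dropped)


def filter_chronic(events: pd.DataFrame, catalog: ConditionCatalog) -> pd.DataFrame:
    """Keep only events whose code carries the catalog's chronic flag."""
    keep = events["code"].isin(catalog.chronic_codes)
    logger.info("filter_chronic: kept %d of %d events", int(keep.sum()), len(events))
    return events.loc[keep].reset_index(drop=True)


def compute_patient_age(
    patients: pd.DataFrame, events: pd.DataFrame, period: tuple[date, date]
) -> pd.Series:
    """Analysis age in years, indexed by patient_id.

    Mean of the ages at the first and last diagnosis dated inside the period;
    for patients without in-period diagnoses, age at the period midpoint.
    """
    start, end = pd.Timestamp(period[0]), pd.Timestamp(period[1])
    birth = patients.set_index("patient_id")["birth_date"]
    if (birth > end).any():
        bad = birth[birth > end].index.tolist()
        raise InputError(f"birth date after period end for patients: {bad[:5]}")
    in_period = events[(events["diagnosis_date"] >= start) & (events["diagnosis_date"] <= end)]
    agg = in_period.groupby("patient_id")["diagnosis_date"].agg(["min", "max"])
    agg = agg.reindex(birth.index)
    midpoint = start + (end - start) / 2
    b = birth.to_numpy()
    age_first = (agg["min"].to_numpy() - b) / np.timedelta64(1, "D") / DAYS_PER_YEAR
    age_last = (agg["max"].to_numpy() - b) / np.timedelta64(1, "D") / DAYS_PER_YEAR
    age_mid = (midpoint - birth) / pd.Timedelta(days=1) / DAYS_PER_YEAR
    age = pd.Series((age_first + age_last) / 2.0, index=birth.index, name="analysis_age")
    return age.fillna(age_mid)


def flag_complete_records(patients: pd.DataFrame) -> pd.DataFrame:
    """Add ``covariates_complete``: tobacco, alcohol, weight and height all
    recorded. Absent columns count as entirely missing."""
    out = patients.copy()
    flag = pd.Series(True, index=out.index)
    for col in COVARIATE_COLUMNS:
        flag &= out[col].notna() if col in out.columns else False
    out["covariates_complete"] = flag
    return out


def _activity_intervals(
    patients: pd.DataFrame, events: pd.DataFrame, period: tuple[date, date]
) -> pd.DataFrame:
    """Per-event activity interval [diagnosis, min(resolution, end_date)],
    truncated at death/transfer, restricted to events intersecting the period."""
    start, end = pd.Timestamp(period[0]), pd.Timestamp(period[1])
    if "end_date" not in patients.columns:
        patients = patients.assign(end_date=pd.NaT)
    ev = events.merge(patients[["patient_id", "end_date"]], on="patient_id", how="inner")
    res = ev["resolution_date"] if "resolution_date" in ev.columns else pd.Series(pd.NaT, index=ev.index)
    bad = res.notna() & (res < ev["diagnosis_date"])
    if bad.any():
        raise InputError(f"{int(bad.sum())} events resolve before diagnosis")
    # censoring: drop events recorded after death/transfer
    ev = ev[ev["end_date"].isna() | (ev["diagnosis_date"] <= ev["end_date"])]
    res = res.loc[ev.index].fillna(_FAR_FUTURE)
    stop = pd.concat([res, ev["end_date"].fillna(_FAR_FUTURE)], axis=1).min(axis=1)
    ev = ev.assign(active_from=ev["diagnosis_date"], active_to=stop)
    in_period = (ev["active_from"] <= end) & (ev["active_to"] >= start)
    return ev.loc[in_period].drop(columns=["end_date"]).reset_index(drop=True)


def select_multimorbid(
    patients: pd.DataFrame,
    events: pd.DataFrame,
    period: tuple[date, date] = ((date(2006, 1, 1)), date(2017, 12, 31)),
    coexistence: str = "strict",
    min_age: float = 18.0,
    min_conditions: int = 2,
) -> Cohort:
    """Build the analysis cohort.

    coexistence='strict' requires at least one pair of distinct chronic
    conditions whose activity intervals overlap inside the period;
    'lenient' merely requires ``min_conditions`` distinct conditions active
    at some time in the period. ``min_conditions=0`` keeps every patient
    (used for population-level estimation on synthetic data).
    Events must already be mapped and chronic-filtered.
    """
    if coexistence not in ("strict", "lenient"):
        raise ConfigError(f"unknown coexistence mode {coexistence!r}")
    start, end = pd.Timestamp(period[0]), pd.Timestamp(period[1])
    ev = _activity_intervals(patients, events, period)
    if ev.empty and min_conditions > 0:
        logger.warning("select_multimorbid: no events intersect the study period")

    # one interval per (patient, condition): earliest onset, latest activity
    per_cond = (
        ev.groupby(["patient_id", "code"])
        .agg(active_from=("active_from", "min"), active_to=("active_to", "max"))
        .reset_index()
    )
    per_cond["clip_from"] = per_cond["active_from"].clip(lower=start)
    per_cond["clip_to"] = per_cond["active_to"].clip(upper=end)

    n_cond = per_cond.groupby("patient_id")["code"].nunique()
    if min_conditions <= 0:
        eligible = set(patients["patient_id"])
    elif coexistence == "lenient" or min_conditions < 2:
        eligible = set(n_cond[n_cond >= min_conditions].index)
    else:
        # strict: some pair of condition intervals overlaps within the period
        pc = per_cond.sort_values(["patient_id", "clip_from"], kind="mergesort")
        prev_max_to = pc.groupby("patient_id")["clip_to"].cummax().shift(1)
        first_of_patient = ~pc["patient_id"].duplicated()
        overlap = (~first_of_patient) & (pc["clip_from"] <= prev_max_to)
        eligible = set(pc.loc[overlap, "patient_id"])
        if min_conditions > 2:
            eligible &= set(n_cond[n_cond >= min_conditions].index)

    pats = patients[patients["patient_id"].isin(eligible)].copy()
    ev_keep = ev[ev["patient_id"].isin(eligible)].reset_index(drop=True)
    age = compute_patient_age(pats, ev_keep, period)
    pats["analysis_age"] = pats["patient_id"].map(age)
    if min_conditions > 0:  # population path (min_conditions=0) keeps everyone
        pats = pats.loc[pats["analysis_age"] >= min_age]
    pats = pats.reset_index(drop=True)
    ev_keep = ev_keep[ev_keep["patient_id"].isin(set(pats["patient_id"]))].reset_index(drop=True)
    pats = flag_complete_records(pats)
    logger.info(
        "select_multimorbid: %d of %d patients selected (%s coexistence, %d events)",
        len(pats), len(patients), coexistence, len(ev_keep),
    )
    return Cohort(patients=pats, events=ev_keep, period=period)
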