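"""Age/sex-adjusted pairwise odds ratios between chronic conditions.

For every unordered pair of conditions with enough patients, a logistic
regression of one condition's presence indicator on the other's, adjusted
for age (continuous years, or age-group categories) and sex, yields the edge
odds ratio exp(beta) and a Wald p-value. Edges are kept when OR >= 1.2 and
p < 1e-5 (risk mode; the fixed threshold plays the role of a Bonferroni-style
guard against the mass significance a large cohort produces), or OR <= 0.8
in protective mode.

Adjusted ORs are not exactly symmetric in which condition is the outcome;
by default the *less prevalent* condition is modelled as the outcome (the
better-conditioned fit), overridable per call.
"""

from __future__ import annotations

import itertools
import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import ConvergenceWarning, PerfectSeparationError

from .cohort import Cohort
from .errors import ConfigError

logger = logging.getLogger("comorbnet")

METADATA_COLUMNS = ("age", "sex")


@dataclass
class EdgeFilter:
    """Edge inclusion thresholds. ``mode`` is 'risk' (keep OR >= min_or) or
    'protective' (keep OR <= max_or); both require p < max_p and each
    condition to have at least ``min_patients`` patients."""

    min_or: float = 1.2
    max_or: float = 0.8
    max_p: float = 1e-5
    min_patients: int = 1000
    mode: str = "risk"

    def __post_init__(self) -> None:
        if self.mode not in ("risk", "protective"):
            raise ConfigError(f"unknown edge filter mode {self.mode!r}")
        if self.mode == "risk" and not self.min_or > 1:
            raise ConfigError("min_or must exceed 1 in risk mode")
        if self.mode == "protective" and not self.max_or < 1:
            raise ConfigError("max_or must be below 1 in protective mode")
        if not (0 < self.max_p < 1):
            raise ConfigError("max_p must lie in (0, 1)")
        if self.min_patients < 0:
            raise ConfigError("min_patients must be nonnegative")

    def passes(self, assoc: "PairAssociation") -> bool:
        if not assoc.valid:
            return False
        if not assoc.p_value < self.max_p:
            return False
        if self.mode == "risk":
            return assoc.odds_ratio >= self.min_or
        return assoc.odds_ratio <= self.max_or


@dataclass
class PairAssociation:
    """Adjusted association for one canonically ordered condition pair."""

    code_a: str
    code_b: str
    n11: int
    n10: int
    n01: int
    n00: int
    n_a: int
    n_b: int
    odds_ratio: float = math.nan
    p_value: float = math.nan
    outcome_code: str = ""
    converged: bool = False
    note: str = ""

    @property
    def valid(self) -> bool:
        return self.converged and math.isfinite(self.odds_ratio) and self.odds_ratio > 0

    @property
    def n_total(self) -> int:
        return self.n11 + self.n10 + self.n01 + self.n00


def build_presence_matrix(cohort: Cohort) -> pd.DataFrame:
    """One row per cohort patient: a 0/1 indicator per condition active
    in-period, plus ``age`` (analysis age) and ``sex`` (1 = male).
    Condition columns are sorted codes; row order follows the patient table."""
    codes = sorted(cohort.events["code"].unique())
    pats = cohort.patients.set_index("patient_id")
    if len(cohort.events):
        pairs = cohort.events[["patient_id", "code"]].drop_duplicates().assign(v=1)
        mat = (
            pairs.pivot(index="patient_id", columns="code", values="v")
            .reindex(index=pats.index, columns=codes)
            .fillna(0)
            .astype(np.int8)
        )
    else:
        mat = pd.DataFrame(0, index=pats.index, columns=codes, dtype=np.int8)
    mat["age"] = pats["analysis_age"].astype(float)
    mat["sex"] = (pats["sex"] == "M").astype(np.int8)
    return mat


def _counts(presence: pd.DataFrame, a: str, b: str) -> tuple[int, int, int, int]:
    xa = presence[a].to_numpy(dtype=bool)
    xb = presence[b].to_numpy(dtype=bool)
    n11 = int(np.sum(xa & xb))
    n10 = int(np.sum(xa & ~xb))
    n01 = int(np.sum(~xa & xb))
    n00 = int(np.sum(~xa & ~xb))
    return n11, n10, n01, n00


def _age_design(presence: pd.DataFrame, age_groups: bool) -> np.ndarray:
    if not age_groups:
        return presence[["age"]].to_numpy(dtype=float)
    bins = [0, 45, 65, 80, np.inf]
    cats = pd.cut(presence["age"], bins=bins, right=False)
    return pd.get_dummies(cats, drop_first=True, dtype=float).to_numpy()


def estimate_pair_or(
    presence: pd.DataFrame,
    pair: tuple[str, str],
    adjust: tuple[str, ...] = ("age", "sex"),
    outcome: str = "less_prevalent",
    age_groups: bool = False,
) -> PairAssociation:
    """Adjusted odds ratio for one pair via logistic regression.

    ``outcome`` picks which condition is the regression outcome:
    'less_prevalent' (default), 'a' or 'b'. Zero cells in the 2x2 table and
    non-convergent fits are flagged invalid (excluded from networks) with an
    infinite/zero OR sentinel where the crude table dictates one.
    """
    a, b = sorted(pair)
    n11, n10, n01, n00 = _counts(presence, a, b)
    n_a, n_b = n11 + n10, n11 + n01
    assoc = PairAssociation(a, b, n11, n10, n01, n00, n_a, n_b)

    if min(n11, n10, n01, n00) == 0:
        # crude OR sentinel: 0 when the numerator vanishes, inf otherwise
        assoc.odds_ratio = 0.0 if (n11 == 0 or n00 == 0) else math.inf
        assoc.note = "zero_cell"
        return assoc

    if outcome == "less_prevalent":
        y_code = a if n_a < n_b else b
    elif outcome in ("a", "b"):
        y_code = a if outcome == "a" else b
    else:
        raise ConfigError(f"unknown outcome convention {outcome!r}")
    x_code = b if y_code == a else a
    assoc.outcome_code = y_code

    y = presence[y_code].to_numpy(dtype=float)
    cols = [presence[x_code].to_numpy(dtype=float)[:, None]]
    if "age" in adjust:
        cols.append(_age_design(presence, age_groups))
    if "sex" in adjust:
        cols.append(presence[["sex"]].to_numpy(dtype=float))
    X = sm.add_constant(np.hstack(cols), prepend=True)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", category=ConvergenceWarning)
            warnings.simplefilter("ignore", category=RuntimeWarning)
            res = sm.Logit(y, X).fit(disp=0, maxiter=200)
    except (PerfectSeparationError, np.linalg.LinAlgError) as exc:
        assoc.note = f"fit_failed: {exc}"
        return assoc
    if not res.mle_retvals.get("converged", False):
        assoc.note = "not_converged"
        return assoc
    assoc.odds_ratio = float(np.exp(res.params[1]))
    assoc.p_value = float(res.pvalues[1])
    assoc.converged = True
    return assoc


def estimate_all_pairs(
    presence: pd.DataFrame,
    edge_filter: EdgeFilter | None = None,
    adjust: tuple[str, ...] = ("age", "sex"),
    outcome: str = "less_prevalent",
    age_groups: bool = False,
) -> list[PairAssociation]:
    """Adjusted associations for all unordered pairs of eligible conditions
    (those with at least ``edge_filter.min_patients`` patients), in canonical
    order. Per-pair failures are logged, never fatal."""
    filt = edge_filter or EdgeFilter()
    codes = [c for c in presence.columns if c not in METADATA_COLUMNS]
    counts = {c: int(presence[c].sum()) for c in codes}
    eligible = sorted(c for c in codes if counts[c] >= filt.min_patients)
    dropped = sorted(set(codes) - set(eligible))
    if dropped:
        logger.info("estimate_all_pairs: %d conditions below min_patients=%d: %s",
                    len(dropped), filt.min_patients, dropped)
    if len(eligible) < 2:
        logger.warning("estimate_all_pairs: fewer than 2 eligible conditions")
        return []
    out = []
    for a, b in itertools.combinations(eligible, 2):
        assoc = estimate_pair_or(presence, (a, b), adjust=adjust, outcome=outcome,
                                 age_groups=age_groups)
        if not assoc.valid:
            logger.info("estimate_all_pairs: pair (%s, %s) excluded (%s)", a, b, assoc.note)
        out.append(assoc)
    return out


def filter_edges(
    associations: list[PairAssociation], edge_filter: EdgeFilter | None = None
) -> list[PairAssociation]:
    """Apply the OR/p-value thresholds; invalid fits never pass."""
    filt = edge_filter or EdgeFilter()
    kept = [a for a in associations if filt.passes(a)]
    logger.info("filter_edges: kept %d of %d pairs (mode=%s)", len(kept), len(associations), filt.mode)
    return kept


def associations_to_frame(associations: list[PairAssociation]) -> pd.DataFrame:
    """Edge-table shape: (code_a, code_b, OR, p, 2x2 counts, margins)."""
    return pd.DataFrame(
        [
            {
                "code_a": a.code_a, "code_b": a.code_b,
                "odds_ratio": a.odds_ratio, "p_value": a.p_value,
                "n11": a.n11, "n10": a.n10, "n01": a.n01, "n00": a.n00,
                "n_a": a.n_a, "n_b": a.n_b,
                "outcome_code": a.outcome_code, "converged": a.converged, "note": a.note,
            }
            for a in associations
        ],
        columns=["code_a", "code_b", "odds_ratio", "p_value", "n11", "n10", "n01",
                 "n00", "n_a", "n_b", "outcome_code", "converged", "note"],
    )
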