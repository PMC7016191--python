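"""Temporal direction of associated condition pairs from diagnosis order.

Over the patients affected by both conditions of a pair, the fraction whose
first in-period diagnosis of A precedes that of B decides the arrow: the
pair is directed A -> B when the fraction is at or above the upper threshold
(default 0.60), B -> A at or below the lower one (default 0.40), and has no
defined temporal direction in between. Same-day first diagnoses carry no
order information and are excluded from the denominator. The cut-points are
inclusive (exactly 0.60 counts as directed); the stricter 0.20/0.80 variant
used for sensitivity analysis is a parameter choice, not separate code.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .cohort import Cohort
from .errors import ConfigError

LABEL_A_TO_B = "a_to_b"
LABEL_B_TO_A = "b_to_a"
LABEL_UNDEFINED = "undefined"


@dataclass
class TemporalTally:
    code_a: str
    code_b: str
    n_a_first: int
    n_b_first: int
    n_same_day: int

    @property
    def n_ordered(self) -> int:
        return self.n_a_first + self.n_b_first

    @property
    def fraction_a_first(self) -> float:
        return self.n_a_first / self.n_ordered if self.n_ordered else float("nan")


@dataclass
class DirectionLabel:
    label: str  # one of a_to_b / b_to_a / undefined
    low: float
    high: float


def _first_dates(cohort: Cohort) -> pd.DataFrame:
    """Earliest in-period diagnosis date per (patient, condition).

    Re-diagnoses after the first are ignored; diagnoses dated before the
    period (conditions already active at period start) carry no in-period
    onset and are excluded."""
    start, end = pd.Timestamp(cohort.period[0]), pd.Timestamp(cohort.period[1])
    ev = cohort.events
    ev = ev[(ev["diagnosis_date"] >= start) & (ev["diagnosis_date"] <= end)]
    return ev.groupby(["patient_id", "code"])["diagnosis_date"].min().rename("first_date")


def tally_order(cohort: Cohort, pair: tuple[str, str]) -> TemporalTally:
    """Diagnosis-order tally for one canonical pair over co-affected patients."""
    a, b = sorted(pair)
    firsts = _first_dates(cohort).reset_index()
    da = firsts[firsts["code"] == a].set_index("patient_id")["first_date"]
    db = firsts[firsts["code"] == b].set_index("patient_id")["first_date"]
    joined = pd.concat([da.rename("a"), db.rename("b")], axis=1, join="inner")
    return TemporalTally(
        code_a=a,
        code_b=b,
        n_a_first=int((joined["a"] < joined["b"]).sum()),
        n_b_first=int((joined["b"] < joined["a"]).sum()),
        n_same_day=int((joined["a"] == joined["b"]).sum()),
    )


def tally_all(cohort: Cohort, pairs: list[tuple[str, str]]) -> list[TemporalTally]:
    """Vectorised tallies for many pairs at once."""
    firsts = _first_dates(cohort).unstack("code")
    out = []
    for pair in pairs:
        a, b = sorted(pair)
        if a not in firsts.columns or b not in firsts.columns:
            out.append(TemporalTally(a, b, 0, 0, 0))
            continue
        sub = firsts[[a, b]].dropna()
        out.append(
            TemporalTally(
                a, b,
                n_a_first=int((sub[a] < sub[b]).sum()),
                n_b_first=int((sub[b] < sub[a]).sum()),
                n_same_day=int((sub[a] == sub[b]).sum()),
            )
        )
    return out


def assign_direction(tally: TemporalTally, low: float = 0.40, high: float = 0.60) -> DirectionLabel:
    """Threshold the a-first fraction into a direction label; a zero ordered
    denominator is necessarily undefined."""
    if not (0.0 < low < high < 1.0):
        raise ConfigError(f"direction thresholds must satisfy 0 < low < high < 1, got {(low, high)}")
    if tally.n_ordered == 0:
        return DirectionLabel(LABEL_UNDEFINED, low, high)
    f = tally.fraction_a_first
    if f >= high:
        return DirectionLabel(LABEL_A_TO_B, low, high)
    if f <= low:
        return DirectionLabel(LABEL_B_TO_A, low, high)
    return DirectionLabel(LABEL_UNDEFINED, low, high)


def direction_table(
    cohort: Cohort,
    pairs: list[tuple[str, str]],
    low: float = 0.40,
    high: float = 0.60,
) -> pd.DataFrame:
    """Tallies + labels for an edge set, in the writer's column layout."""
    rows = []
    for tally in tally_all(cohort, pairs):
        lab = assign_direction(tally, low=low, high=high)
        rows.append(
            {
                "code_a": tally.code_a, "code_b": tally.code_b,
                "n_a_first": tally.n_a_first, "n_b_first": tally.n_b_first,
                "n_same_day": tally.n_same_day,
                "fraction_a_first": tally.fraction_a_first,
                "label": lab.label,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["code_a", "code_b", "n_a_first", "n_b_first", "n_same_day",
                 "fraction_a_first", "label"],
    )
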