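"""Adjusted odds-ratio estimation and edge filtering."""

import math

import numpy as np
import pandas as pd
import pytest

from comorbnet.association import (
    EdgeFilter,
    PairAssociation,
    build_presence_matrix,
    estimate_all_pairs,
    estimate_pair_or,
    filter_edges,
)
from comorbnet.cohort import select_multimorbid
from comorbnet.errors import ConfigError
from comorbnet.synthetic import generate_cohort

from .conftest import PERIOD, make_diagnoses, make_patients, two_condition_config


def presence_from_counts(n11, n10, n01, n00, seed=0):
    """Presence frame realizing an exact 2x2 table, with age/sex covariates
    unrelated to the conditions."""
    rng = np.random.default_rng(seed)
    n = n11 + n10 + n01 + n00
    a = np.r_[np.ones(n11), np.ones(n10), np.zeros(n01), np.zeros(n00)]
    b = np.r_[np.ones(n11), np.zeros(n10), np.ones(n01), np.zeros(n00)]
    return pd.DataFrame(
        {
            "A01": a.astype(np.int8),
            "B01": b.astype(np.int8),
            "age": rng.uniform(20, 90, n),
            "sex": rng.integers(0, 2, n),
        }
    )


class TestEstimatePair:
    def test_unadjusted_fit_matches_closed_form_2x2_or(self):
        presence = presence_from_counts(50, 50, 50, 850)
        assoc = estimate_pair_or(presence, ("A01", "B01"), adjust=())
        assert assoc.odds_ratio == pytest.approx(17.0, abs=1e-6)
        assert (assoc.n11, assoc.n10, assoc.n01, assoc.n00) == (50, 50, 50, 850)

    def test_adjusted_equals_crude_under_balanced_covariates(self):
        """When the empirical covariate distribution is identical in all four
        2x2 cells, the covariates carry no information and the adjusted OR
        equals the crude OR to solver precision."""
        counts = {"n11": 120, "n10": 250, "n01": 180, "n00": 950}
        ages = np.array([30, 40, 50, 60, 70] * 2, dtype=float)
        sexes = np.array([0, 1] * 5, dtype=float)
        blocks = []
        for key, n in counts.items():
            a, b = int(key[1]), int(key[2])
            reps = n // 10
            blocks.append(pd.DataFrame({"A01": a, "B01": b,
                                        "age": np.tile(ages, reps),
                                        "sex": np.tile(sexes, reps)}))
        presence = pd.concat(blocks, ignore_index=True)
        adjusted = estimate_pair_or(presence, ("A01", "B01"))
        crude = (counts["n11"] * counts["n00"]) / (counts["n10"] * counts["n01"])
        assert adjusted.odds_ratio == pytest.approx(crude, rel=1e-6)

    def test_adjusted_close_to_crude_when_generator_has_no_covariate_effects(self):
        """With zero planted age/sex effects the covariates are independent of
        the conditions, so adjustment moves the OR only by the finite-sample
        covariate-condition correlation (order 1/sqrt(n))."""
        config = two_condition_config(n=30_000, log_or=math.log(2.0), seed=6)
        patients, diagnoses, _ = generate_cohort(config)
        cohort = select_multimorbid(patients, diagnoses, config.study_period, min_conditions=0)
        presence = build_presence_matrix(cohort)
        adjusted = estimate_pair_or(presence, ("A01", "B01"))
        crude = (adjusted.n11 * adjusted.n00) / (adjusted.n10 * adjusted.n01)
        assert adjusted.odds_ratio == pytest.approx(crude, rel=5e-3)

    def test_planted_log_or_recovered(self):
        config = two_condition_config(n=50_000, log_or=math.log(2.0), seed=0)
        patients, diagnoses, _ = generate_cohort(config)
        cohort = select_multimorbid(patients, diagnoses, config.study_period, min_conditions=0)
        assoc = estimate_pair_or(build_presence_matrix(cohort), ("A01", "B01"))
        assert 1.8 <= assoc.odds_ratio <= 2.2

    def test_independent_conditions_give_or_near_one(self):
        config = two_condition_config(n=20_000, log_or=0.0, seed=13)
        patients, diagnoses, _ = generate_cohort(config)
        cohort = select_multimorbid(patients, diagnoses, config.study_period, min_conditions=0)
        assoc = estimate_pair_or(build_presence_matrix(cohort), ("A01", "B01"))
        assert assoc.p_value > 1e-5
        assert 0.9 < assoc.odds_ratio < 1.1

    def test_zero_cell_flagged_and_invalid(self):
        presence = presence_from_counts(0, 60, 60, 880)
        assoc = estimate_pair_or(presence, ("A01", "B01"))
        assert not assoc.valid
        assert assoc.note == "zero_cell"
        assert assoc.odds_ratio == 0.0
        inf_assoc = estimate_pair_or(presence_from_counts(60, 0, 60, 880), ("A01", "B01"))
        assert not inf_assoc.valid
        assert inf_assoc.odds_ratio == math.inf

    def test_row_order_invariance(self):
        presence = presence_from_counts(80, 70, 60, 790, seed=5)
        shuffled = presence.sample(frac=1.0, random_state=1)
        a1 = estimate_pair_or(presence, ("A01", "B01"))
        a2 = estimate_pair_or(shuffled, ("A01", "B01"))
        assert a1.odds_ratio == pytest.approx(a2.odds_ratio, rel=1e-10)

    def test_outcome_convention_is_less_prevalent_with_override(self):
        presence = presence_from_counts(50, 200, 20, 730)  # A01 has 250, B01 has 70
        assert estimate_pair_or(presence, ("A01", "B01")).outcome_code == "B01"
        assert estimate_pair_or(presence, ("A01", "B01"), outcome="a").outcome_code == "A01"
        with pytest.raises(ConfigError):
            estimate_pair_or(presence, ("A01", "B01"), outcome="nope")


class TestPresenceMatrix:
    def test_indicators_and_shape(self):
        patients = make_patients([("p1", "F", "1950-01-01"), ("p2", "M", "1940-01-01")])
        events = make_diagnoses(
            [("p1", "T90", "2007-01-01"), ("p1", "K86", "2008-01-01"),
             ("p2", "K86", "2009-01-01"), ("p2", "F83", "2010-01-01")]
        )
        cohort = select_multimorbid(patients, events, PERIOD)
        presence = build_presence_matrix(cohort)
        assert len(presence) == 2
        assert presence.loc["p1", ["F83", "K86", "T90"]].tolist() == [0, 1, 1]
        assert presence.loc["p2", ["F83", "K86", "T90"]].tolist() == [1, 1, 0]
        assert presence.loc["p2", "sex"] == 1

    def test_column_sums_equal_enumerated_counts(self, small_default_cohort):
        config, patients, diagnoses, _ = small_default_cohort
        cohort = select_multimorbid(patients, diagnoses, config.study_period)
        presence = build_presence_matrix(cohort)
        expected = cohort.events.groupby("code")["patient_id"].nunique()
        for code in expected.index:
            assert presence[code].sum() == expected[code]


class TestAllPairsAndFilter:
    def test_pair_count_and_determinism(self):
        rng = np.random.default_rng(0)
        n = 600
        presence = pd.DataFrame(
            {f"C{i:02d}": rng.integers(0, 2, n).astype(np.int8) for i in range(5)}
        )
        presence["age"] = rng.uniform(20, 90, n)
        presence["sex"] = rng.integers(0, 2, n)
        filt = EdgeFilter(min_patients=10)
        first = estimate_all_pairs(presence, filt)
        second = estimate_all_pairs(presence, filt)
        assert len(first) == 10
        assert [(a.code_a, a.code_b, a.odds_ratio) for a in first] == [
            (a.code_a, a.code_b, a.odds_ratio) for a in second
        ]

    def test_condition_below_min_patients_in_no_pair(self):
        rng = np.random.default_rng(1)
        n = 5000
        presence = pd.DataFrame(
            {
                "A01": rng.integers(0, 2, n).astype(np.int8),
                "B01": rng.integers(0, 2, n).astype(np.int8),
                "C01": (rng.random(n) < 900 / n).astype(np.int8),
            }
        )
        presence["age"] = rng.uniform(20, 90, n)
        presence["sex"] = rng.integers(0, 2, n)
        assert int(presence["C01"].sum()) < 1000
        pairs = estimate_all_pairs(presence, EdgeFilter(min_patients=1000))
        codes = {c for a in pairs for c in (a.code_a, a.code_b)}
        assert "C01" not in codes

    def test_fewer_than_two_eligible_conditions_gives_empty_list(self):
        rng = np.random.default_rng(2)
        presence = pd.DataFrame({"A01": np.ones(50, dtype=np.int8)})
        presence["age"] = rng.uniform(20, 90, 50)
        presence["sex"] = rng.integers(0, 2, 50)
        assert estimate_all_pairs(presence, EdgeFilter(min_patients=1000)) == []

    @pytest.mark.parametrize(
        "odds_ratio,p_value,mode,expected",
        [
            (1.19, 1e-9, "risk", False),
            (1.2, 1e-9, "risk", True),
            (2.0, 1e-3, "risk", False),
            (0.7, 1e-8, "protective", True),
            (0.85, 1e-8, "protective", False),
        ],
    )
    def test_filter_thresholds(self, odds_ratio, p_value, mode, expected):
        assoc = PairAssociation("A01", "B01", 10, 10, 10, 10, 20, 20,
                                odds_ratio=odds_ratio, p_value=p_value, converged=True)
        filt = EdgeFilter(mode=mode)
        assert (filter_edges([assoc], filt) == [assoc]) is expected

    def test_tightening_min_or_shrinks_edge_set(self):
        rng = np.random.default_rng(3)
        assocs = [
            PairAssociation(f"A{i}", f"B{i}", 10, 10, 10, 10, 20, 20,
                            odds_ratio=float(np.exp(rng.normal(0.3, 0.5))),
                            p_value=float(10 ** rng.uniform(-12, -2)), converged=True)
            for i in range(200)
        ]
        previous = None
        for min_or in (1.2, 1.4, 1.6, 1.8, 2.0):
            kept = {(a.code_a, a.code_b) for a in filter_edges(assocs, EdgeFilter(min_or=min_or))}
            if previous is not None:
                assert kept <= previous
            previous = kept

    def test_invalid_filter_configs_rejected(self):
        with pytest.raises(ConfigError):
            EdgeFilter(min_or=0.9, mode="risk")
        with pytest.raises(ConfigError):
            EdgeFilter(max_or=1.1, mode="protective")
        with pytest.raises(ConfigError):
            EdgeFilter(max_p=0.0)
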