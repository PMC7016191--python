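from __future__ import annotations

import math
from datetime import date

import pandas as pd
import pytest

from comorbnet.cohort import ConditionCatalog
from comorbnet.synthetic import SimulationConfig, generate_cohort

PERIOD = (date(2006, 1, 1), date(2017, 12, 31))


def make_patients(rows):
    """rows: list of (patient_id, sex, birth_date[, end_date]) tuples."""
    recs = []
    for row in rows:
        pid, sex, birth = row[:3]
        end = row[3] if len(row) > 3 else None
        recs.append(
            {"patient_id": pid, "sex": sex,
             "birth_date": pd.Timestamp(birth),
             "end_date": pd.Timestamp(end) if end else pd.NaT}
        )
    return pd.DataFrame(recs)


def make_diagnoses(rows):
    """rows: list of (patient_id, code, diagnosis_date[, resolution_date])."""
    recs = []
    for row in rows:
        pid, code, dx = row[:3]
        res = row[3] if len(row) > 3 else None
        recs.append(
            {"patient_id": pid, "code": code,
             "diagnosis_date": pd.Timestamp(dx),
             "resolution_date": pd.Timestamp(res) if res else pd.NaT}
        )
    return pd.DataFrame(recs)


@pytest.fixture()
def toy_catalog():
    conditions = pd.DataFrame(
        {
            "code": ["T90", "K86", "F83", "N94", "R74"],
            "label": ["diabetes", "hypertension", "retinopathy", "neuropathy", "acute URI"],
            "system": ["ICPC-2"] * 5,
            "chronic": [1, 1, 1, 1, 0],
        }
    )
    mapping = pd.DataFrame(
        {
            "source_system": ["ICD-10", "ICD-10"],
            "source_code": ["E11", "I10"],
            "target_system": ["ICPC-2", "ICPC-2"],
            "target_code": ["T90", "K86"],
        }
    )
    return ConditionCatalog(conditions, mapping)


def two_condition_config(n=50_000, log_or=math.log(2.0), seed=0, **kwargs):
    """Minimal planted-pair configuration with null age/sex effects."""
    return SimulationConfig(
        n_patients=n,
        conditions={"A01": "Condition A", "B01": "Condition B"},
        intercepts={"A01": -1.0, "B01": -1.2},
        age_coefficients={"A01": 0.0, "B01": 0.0},
        sex_coefficients={"A01": 0.0, "B01": 0.0},
        pair_log_ors={("A01", "B01"): log_or} if log_or else {},
        seed=seed,
        **kwargs,
    )


@pytest.fixture(scope="session")
def small_default_cohort():
    """One modest default-parameter synthetic dataset shared across tests."""
    from comorbnet.synthetic import default_config

    config = default_config(n_patients=8000, seed=20060101)
    patients, diagnoses, truth = generate_cohort(config)
    return config, patients, diagnoses, truth
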