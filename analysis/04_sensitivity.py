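#!/usr/bin/env python
"""Sensitivity analyses on the simulated extraction.

Three variations of the main analysis, mirroring the checks a registry study
would run: (a) sweeping the minimum OR from 1.2 to 2.0 and counting nodes and
edges in both network conventions, (b) restricting to patients with complete
lifestyle covariates, and (c) tightening the temporal-direction thresholds
from 0.40/0.60 to 0.20/0.80 on a cohort with uniformly drawn ordering
propensities and measuring how many directed labels survive.
Outputs land under results/sensitivity/.
"""

import sys
from pathlib import Path

import pandas as pd

from comorbnet import io as cio
from comorbnet.cohort import select_multimorbid
from comorbnet.pipeline import PipelineConfig, run_pipeline
from comorbnet.synthetic import generate_cohort, uniform_ordering_config
from comorbnet.temporal import LABEL_UNDEFINED, direction_table

INDIR = Path("results/synthetic")
OUTDIR = Path("results/sensitivity")
SEED = 2017


def or_sweep(patients, diagnoses) -> pd.DataFrame:
    rows = []
    for min_or in (1.2, 1.4, 1.5, 1.6, 1.8, 2.0):
        for complete_only in (False, True):
            cfg = PipelineConfig(min_or=min_or, complete_records_only=complete_only)
            res = run_pipeline(cfg, patients, diagnoses)
            rows.append(
                {
                    "min_or": min_or,
                    "complete_records_only": complete_only,
                    "cohort": res.cohort.size,
                    "nodes": res.undirected.n_nodes,
                    "edges_undirected": res.undirected.n_edges,
                    "arcs_directed": res.directed.n_edges,
                }
            )
    return pd.DataFrame(rows)


def direction_sensitivity() -> pd.DataFrame:
    config = uniform_ordering_config(n_patients=20_000, seed=SEED)
    patients, diagnoses, _ = generate_cohort(config)
    cohort = select_multimorbid(patients, diagnoses, config.study_period)
    pairs = [tuple(sorted(p)) for p in config.ordering_propensity]
    rows = []
    for low, high in ((0.40, 0.60), (0.20, 0.80)):
        table = direction_table(cohort, pairs, low=low, high=high)
        rows.append(
            {
                "low": low,
                "high": high,
                "pairs": len(table),
                "directed": int((table["label"] != LABEL_UNDEFINED).sum()),
            }
        )
    return pd.DataFrame(rows)


def main() -> int:
    if not (INDIR / "patients.tsv").exists():
        print("run analysis/01_simulate_cohort.py first", file=sys.stderr)
        return 1
    patients = cio.read_patients(INDIR / "patients.tsv")
    diagnoses = cio.read_diagnoses(INDIR / "diagnoses.tsv")
    OUTDIR.mkdir(parents=True, exist_ok=True)

    sweep = or_sweep(patients, diagnoses)
    cio.write_table(sweep, OUTDIR / "or_threshold_sweep.tsv")
    print("OR-threshold sweep (edge sets shrink monotonically; directed arc "
          "counts exceed undirected edge counts at every threshold):")
    print(sweep.to_string(index=False))

    sens = direction_sensitivity()
    cio.write_table(sens, OUTDIR / "direction_threshold_sensitivity.tsv")
    n40, n20 = sens["directed"].tolist()
    reduction = 100 * (1 - n20 / n40) if n40 else 0.0
    print("\ndirection-threshold sensitivity (uniform ordering propensities):")
    print(sens.to_string(index=False))
    print(f"tightening 0.40/0.60 -> 0.20/0.80 removed {reduction:.0f}% of directed labels")
    print(f"\noutputs written to {OUTDIR}/")
    return 0


if __name__ == "__main__":
    sys.exit(main())
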