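# comorbnet

Multimorbidity comorbidity networks from longitudinal primary-care
diagnosis records.

Multimorbidity — two or more chronic conditions in the same patient — is
usually studied one disease pair at a time. This package takes the network
view: every chronic condition is a node, and two conditions are linked when
they co-occur in patients more often than their prevalences explain. From a
patient table (id, sex, birth date, optional death/transfer date, lifestyle
covariates) and a diagnosis table (patient id, condition code, diagnosis
date, optional resolution date) it builds the full analysis chain used by
registry-scale multimorbidity studies:

1. **Cohort** — map codes between classification systems (e.g. ICD-10 →
   ICPC-2), keep chronic conditions, select adults with ≥ 2 coexistent
   chronic conditions active in the study period, truncate at
   death/transfer, and compute each patient's analysis age (mean of the ages
   at the first and last in-period diagnosis, else the age at the period
   midpoint).
2. **Edges** — for every condition pair, a logistic regression of one
   condition's presence indicator on the other's, adjusted for age and sex:

   logit P(Y_b = 1) = β₀ + β₁ Y_a + β₂ · age + β₃ · sex

   The edge weight is the adjusted odds ratio OR = exp(β₁) with a Wald
   p-value. Risk edges keep OR ≥ 1.2 and p < 1e-5 (protective mode: OR ≤
   0.8); conditions with fewer than 1000 patients are excluded.
3. **Direction** — over the patients having both conditions, the fraction
   whose first diagnosis of *a* precedes that of *b*: ≥ 0.60 gives the arc
   a → b, ≤ 0.40 gives b → a, anything between is an undefined direction and
   is drawn as a double arrow (two arcs, counted twice).
4. **Networks** — undirected and directed graphs, focal-condition subnets
   (closed neighbourhood of one condition), and disease trajectories:
   one-step predecessors of a focal condition plus directed walks up to
   three arcs downstream, restricted to OR ≥ 1.5.
5. **Metrics** — degree, local clustering 2eᵢ/(kᵢ(kᵢ−1)), damped PageRank
   PR(g) = (1−d)/N + d·Σ_{u→g} PR(u)/N_out(u) with d = 0.85 (weighted by
   arc ORs), and per network: density Σmᵢⱼ/(n(n−1)), diameter, average
   clustering, Freeman degree centralization (0 = regular graph, 100 =
   star), as a percentage.

Real primary-care registries are access-restricted, so the package also
ships a **synthetic EHR generator** (`comorbnet.synthetic`) with planted
structure — per-condition age/sex-dependent prevalence, a pairwise log-odds
association matrix, diagnosis-order biases, death censoring and missing
lifestyle covariates — plus the planted truth, so every stage is testable by
parameter recovery. A small packaged reference edge list (37 directed links
around type 2 diabetes, ICPC-2 code T90) provides a worked example with
published degree and subnet counts.

## Worked example

The analysis is organised as numbered drivers over the library:

```bash
python analysis/01_simulate_cohort.py       # synthetic extraction -> results/synthetic/
python analysis/02_build_networks.py        # full pipeline        -> results/networks/
python analysis/03_reference_t2dm_networks.py  # packaged reference -> results/reference/
python analysis/04_sensitivity.py           # threshold sweeps     -> results/sensitivity/
```

`03_reference_t2dm_networks.py` rebuilds the directed type 2 diabetes
network from the packaged edge list and prints:

```
reference edge list: 37 direct links of T90 (20 directed, 17 undefined direction)
undirected ego edges: 37 (T90 degree 37)

OR >= 1.5: directed network 23 nodes, 32 arcs (undefined pairs double-counted)
  T90 in-degree 12, out-degree 20
  T90 subnet: 23 nodes

OR >= 2.0: directed network 11 nodes, 13 arcs (undefined pairs double-counted)
  T90 in-degree 4, out-degree 9
  T90 subnet: 11 nodes
```

Reading: at the OR ≥ 1.5 threshold, 12 arcs point into diabetes (conditions
diagnosed first in ≥ 60% of co-affected patients, e.g. obesity/overweight,
OR 2.6) and 20 point out of it (complications diagnosed after, e.g.
retinopathy, OR 23.8); pairs with no clear temporal order contribute one arc
each way. Raising the threshold to 2 shrinks the subnet from 23 to 11
conditions.

`02_build_networks.py` runs the same pipeline on the synthetic extraction
(50,000 patients) and recovers the planted association structure: the five
strongly planted pairs pass the edge filter, the weakest planted pair is
attenuated below OR 1.2 by the multimorbidity selection (see
`docs/methods.md`), and no spurious edge appears.

A thin CLI wraps the same functions for shell use:

```bash
comorbnet generate --n-patients 50000 --seed 1 --out data/
comorbnet build --patients data/patients.tsv --diagnoses data/diagnoses.tsv \
    --min-or 1.5 --focal T90 --out out/
comorbnet subnet --network out/network_undirected.json --focal T90 --out sub.json
comorbnet fixture            # print the packaged reference edge list
```

## Layout

- `src/comorbnet/` — the library: `synthetic`, `cohort`, `association`,
  `temporal`, `network`, `metrics`, `pipeline`, `io`, `cli`, packaged data
  under `data/`.
- `analysis/` — numbered narrative drivers writing under `results/`.
- `docs/methods.md` — model, conventions, numerical choices, known
  artifacts and limitations.
- `tests/` — pytest suite with independent oracles in `tests/_oracles.py`.
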