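# Methods

## Statistical model

The object of inference is, for every unordered pair of chronic conditions
(a, b), the age- and sex-adjusted odds ratio of their co-occurrence across a
multimorbid adult cohort. One condition of the pair is the outcome of a
logistic regression; the other enters as a binary exposure together with age
and sex:

    logit P(Y = 1) = β0 + β1 X + β2 age + β3 male

with OR = exp(β1) and a Wald p-value on β1. Conventions:

- **Outcome choice.** Adjusted ORs are not exactly symmetric in which
  condition is modelled. The default outcome is the *less prevalent*
  condition of the pair (the better-conditioned fit; rare outcome, common
  exposure). `estimate_pair_or(..., outcome=...)` overrides this per call.
- **Age.** Continuous analysis age in years by default; an age-group
  categorical design (18–44, 45–64, 65–79, 80+) is available via
  `age_groups=True`. Analysis age is the mean of the ages at the first and
  last diagnosis dated inside the study period, or the age at the period
  midpoint for patients without in-period diagnoses. Ages are exact day
  counts divided by 365.25.
- **Significance.** The edge filter uses the fixed threshold p < 1e-5 as a
  Bonferroni-style guard: registry-scale cohorts make trivial associations
  significant, so the cut is deliberately far below 0.05 and is *not*
  recomputed from the pair count. Default OR thresholds: risk ≥ 1.2
  (configurable 1.2–2.0), protective ≤ 0.8 (0.8–0.5).
- **Degenerate fits.** A zero cell in the 2×2 table, perfect separation or
  non-convergence flags the pair invalid (sentinel OR 0/∞, no continuity
  correction); invalid pairs never enter a network. Conditions with fewer
  than 1000 patients (configurable) are excluded from all pairs.

## Cohort construction

A patient enters the cohort when at least two distinct chronic conditions
are *coexistent* within the study period (default 2006-01-01 to 2017-12-31).
Each (patient, condition) has an activity interval from first diagnosis to
resolution (missing resolution = still active), truncated at death/transfer;
diagnoses recorded after the end date are dropped rather than rejected.
Two readings of "coexistent" are implemented:

- `strict` (default): some pair of condition intervals overlaps inside the
  period — simultaneous activity;
- `lenient`: both conditions active at some time in the period, not
  necessarily together.

The adult filter (≥ 18 years) applies to the computed analysis age. The
`min_conditions=0` path skips all selection and is the population-level
estimation mode used by the recovery checks (see "Selection effects" below).
Code mapping across classification systems takes a user-supplied table
(packaged: an illustrative ~40-code ICPC-2 catalog with chronic flags and a
small ICD-10 crosswalk); one-to-many mappings require an explicit priority
column, unmapped codes are dropped and counted.

## Temporal direction

For patients with both conditions of an edge, the earliest in-period
diagnosis date of each condition defines the order; re-diagnoses are
ignored and same-day firsts carry no information (excluded from the
denominator). With f = fraction of a-before-b among ordered patients:
f ≥ 0.60 → a→b, f ≤ 0.40 → b→a, otherwise undefined. Both cut-points are
*inclusive* (exactly 0.60 is directed) — the verbal rule is ambiguous at the
boundary and the inclusive reading keeps the two directed regions symmetric;
`assign_direction(low=..., high=...)` takes the stricter 0.20/0.80
sensitivity variant or any other pair. An undefined-direction edge becomes
two arcs in the directed network, so directed networks have more edges than
the undirected network at the same OR threshold; a pair's single adjusted OR
is reused as the weight of its arc(s).

## Networks, subnets, trajectories

Networks are simple weighted graphs (weight = OR); nodes with no passing
edge are omitted, so printed node counts equal incident nodes. A focal
subnet is the induced subgraph on the focal condition plus its neighbours,
*including* edges among the neighbours (closed neighbourhood). A trajectory
for a focal condition keeps arcs with OR ≥ 1.5 (configurable) and reports
(i) one-step predecessor arcs into the focal node and (ii) every arc lying
on a directed walk of at most 3 arcs out of it, with the number of distinct
immediate predecessors per reached condition; undefined-direction arcs are
traversable both ways, and cycles are cut by the depth bound.

## Node and network statistics

- **Clustering**: 2eᵢ/(kᵢ(kᵢ−1)) on the undirected simple view, 0 when
  kᵢ < 2; the network value is the *mean* of per-node coefficients, not the
  transitivity (triangle) ratio — the two differ and the tests pin the mean.
- **PageRank**: PR(g) = (1−d)/N + d·Σ_{u→g} PR(u)/N_out(u), d = 0.85, by
  power iteration (L1 tolerance 1e-12, max 1000 iterations, error with the
  residual on non-convergence). Undirected edges are bi-directional. In the
  weighted variant (default) a node's mass splits over out-arcs
  proportionally to OR weights; `weighted=False` gives the unweighted
  recursion. Dangling nodes shed their mass uniformly over all nodes — the
  recursion is silent about them, and the uniform policy is what keeps the
  scores summing to 1 (asserted to 1e-9). The same policy is used by the
  dense linear-solve oracle in the tests.
- **Density**: Σᵢⱼ mᵢⱼ / (n(n−1)) of the adjacency matrix — for directed
  networks the double arcs of undefined pairs count twice.
- **Centralization**: Freeman degree centralization Σᵢ(k_max − kᵢ) divided
  by the maximum possible sum (n−1)(n−2), as a percentage; computed on the
  undirected view; 0 by convention for n < 3. 0 for any regular (incl.
  complete) graph, 100 for a star.
- **Diameter**: unweighted shortest paths on the largest connected component
  of the undirected view, with a `disconnected` flag; a single node has
  diameter 0.

## Synthetic cohort generator

The generator emulates a primary-care extraction with known truth. Per
patient: age ~ Uniform(18, 90) (age at the period midpoint; birth date
derived), sex ~ Bernoulli(0.5). Condition presence is sequential in the
configured order:

    P(condition j | previous) = expit(intercept_j + age_coef_j·age
                                      + sex_coef_j·male
                                      + Σ_{i<j present} pair_log_or(i, j))

so each planted log-OR is the *conditional* log-odds ratio given the earlier
conditions — a deliberate choice over a joint (Ising-type) sampler: it is
fast, exact, and the recovery tests target the induced association with a
documented tolerance. Diagnosis dates are uniform over the period. Ordering
bias: for a configured ordered pair (a, b) with propensity p, dates are
swapped where needed so a comes first with probability p among co-affected
patients — presence marginals are untouched, so association and ordering are
decoupled. When configured pairs share a condition, swaps are applied in
reverse configuration order so the *first-listed* pair's propensity is exact
and later-listed ones are perturbed toward 0.5; configurations meant for
ordering recovery should use disjoint pairs (as `uniform_ordering_config`
does).

Default study conditions (`default_config`): 50,000 patients, ten ICPC-2
chronic conditions with intercepts giving 6–47% prevalence at adult ages,
age effects 0.01–0.05 log-odds/year, sex effects ±0.4, six planted pair
log-ORs between log 1.6 and log 3, three ordering propensities 0.75–0.85,
death hazard 0.01/year, 30% of patients missing lifestyle covariates.
Resolution dates are off by default (chronic conditions stay active); a
`resolution_fraction` emits them for testing the coexistence filter.
`uniform_ordering_config`: 30 disjoint pairs with ordering propensities ~
Uniform(0.15, 0.85) — most mass between the strict and default direction
bands, a minority beyond, so tightening 0.40/0.60 → 0.20/0.80 removes the
large majority (~80–90%) of directed labels but not all.

### What the generator does and does not emulate

It reproduces the statistical structure the estimator targets (logistic
prevalence in age/sex, pairwise conditional log-ORs, diagnosis-order bias,
censoring, covariate missingness). It does **not** model disease natural
history, calendar-time incidence trends, coding noise, correlated covariate
missingness, or age-dependent mortality. Passing recovery tests therefore
demonstrate estimator correctness under the declared generative model, not
fidelity of any particular real-world network.

### Selection and measurement artifacts (intentional, documented)

Three real-data phenomena are reproduced by the generator and matter for
interpreting tests:

- **Berkson-type selection.** Conditioning on ≥ 2 conditions induces
  negative association among otherwise independent conditions and attenuates
  planted positive ORs (e.g. a planted log-OR of 0.47 can fall below the 1.2
  edge threshold in the multimorbid cohort). Parameter-recovery checks
  therefore estimate on the full population (`min_conditions=0`); the
  planted-edge pipeline check uses strong planted effects that survive
  selection.
- **Shared censoring.** Truncating diagnoses at a patient's death time makes
  observed presence of independent conditions positively correlated (both
  require diagnosis before death) — ORs up to ~1.2 at n = 50,000 from a
  1%/year hazard alone. The null type-I check runs with the death hazard at
  0 because its premise is independence of *observed* presence; the
  artifact is a property of censored EHR data, not of the estimator.
- **Analysis-age measurement error.** The analysis age is a noisy proxy of
  the age that generated the data, so adjustment leaves a residual
  association of order β_a·β_b·Var(error) (≲ 0.03 log-OR here) plus an
  Op(n^{-1/2}) finite-sample term; the adjusted-equals-crude oracle check is
  exact only under covariates balanced across the 2×2 cells, and the
  generator-level check allows 0.5% relative slack.

## Problem sizes and numerics

Recovery and null checks run at n = 50,000 patients (2 and 10 conditions;
5 replicates for the null); the ordering and directionality checks at
n = 5,000–20,000; metric oracles on 50 random graphs with ≤ 15 nodes
(tolerance 1e-8 against enumeration and dense linear solves). Logistic fits
use Newton iterations (statsmodels, maxiter 200); convergence failures are
flagged per pair, never fatal to a run. Dates are ISO-8601 throughout;
deterministic ordering (sorted codes, canonical pairs, stable sorts) makes
same-seed runs byte-identical.

## Known limitations

- Directionality reflects *recorded* diagnosis order, not disease onset;
  conditions active before the study period have no in-period onset and drop
  out of the ordering denominator (no left-truncation correction).
- The packaged condition catalog and ICD-10 crosswalk are illustrative, not
  a curated chronicity list or a full mapping; users supply their own tables
  for real analyses.
- One model is fitted per unordered pair; direction labels reuse the pair OR
  rather than estimating direction-specific effects.
- No confounders beyond age and sex; stratified (sex/age-group) networks are
  cohort filters over the same pipeline.
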