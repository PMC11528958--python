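# psnet

Patient-sharing network analysis for visit-level primary-care registries.

`psnet` turns a registry of visits (one row per visit: patient id,
professional id, date, municipality, occupation code, service type, ICD-10
and ICPC-2 codes, mental-health service flag) into professional-level
patient-sharing networks and analyzes them:

- **`psnet.synthetic`** — generates synthetic registries with configurable
  diagnosis-group mixes, occupation/municipality structure, visit-count
  distributions and deliberately dirty rows, plus networks simulated from
  dyad-independent ERGMs with known coefficients (for parameter-recovery
  testing).
- **`psnet.cohort`** — patient identification (ICD-10 chapter F minus
  dementia/retardation/developmental ranges, ICPC-2 chapter P minus an
  exclusion list, or a flagged service type) and the exclusion cascade
  (home-care, undefined service, occupational health, missing professional
  info, excluded occupations, single-visit and single-professional
  patients), with a step-by-step `FilterReport`. Diagnosis subgroups:
  substance use F10–F19, psychotic F20–F29, depressive F30–F39 — a
  subgroup keeps *all* visits of its member patients.
- **`psnet.network`** — modal occupation/municipality resolution with seeded
  tie-breaks, bipartite patient–professional graph, and projection to an
  undirected professional network where an edge requires at least
  `min_shared` (default 5) distinct common patients; isolates kept by
  default; small-component pruning and Fruchterman–Reingold layout export
  for figures.
- **`psnet.metrics`** — nodes, edges, mean degree, density, mean geodesic
  distance (reachable pairs), global transitivity, unnormalized mean
  betweenness, and per-occupation relative degree/betweenness ratios.
- **`psnet.resampling`** — size-matched nulls: the all-patients cohort is
  repeatedly downsampled to a subgroup's patient count and rebuilt with
  identical settings; observed statistics are tested against the M sampled
  values with a one-sample Wilcoxon signed-rank test and an exact sign
  test. *Caveat:* both are anticonservative when the observed value is
  exchangeable with the null draws; the calibrated Monte-Carlo `rank_p` is
  reported alongside.
- **`psnet.ergm`** — dyad-independent ERGMs (`edges`, `nodefactor`,
  uniform/differential `nodematch`) fitted by exact dyadic maximum
  likelihood (Newton–Raphson, gradient tolerance 1e-8) with Wald CIs,
  AIC/BIC (BIC sample size = number of dyads), separation detection
  (infinite coefficients reported with one-sided intervals), per-dyad
  Bernoulli simulation, and goodness-of-fit envelopes for degree,
  edgewise shared partners and geodesic distance distributions.
- **`psnet.pipeline` / `psnet.cli`** — end-to-end orchestration with a
  master seed deriving independent per-stage seeds; every run writes a
  manifest with SHA-256 hashes of all artifacts (byte-identical across
  repeated runs with the same seed).

## Test

```sh
python -m pytest -q tests/
```

Note: `tests/test_acceptance.py::test_criterion_5_resampling_test_validity`
fails by design — it asserts a type-I-error calibration that the specified
one-sample Wilcoxon comparison cannot achieve (the test is anticonservative
when the observed value is exchangeable with the null draws); see the test
docstring. All other tests pass.

## CLI

```sh
# generate a synthetic registry
psnet simulate --patients 2000 --professionals 300 --seed 1 --out registry.tsv

# filter to the mental-health/substance-use cohort
psnet filter --input registry.tsv --out cohort.tsv --report filter_report.tsv

# one subgroup network + statistics
psnet network --input cohort.tsv --subgroup depressive --out depressive.graphml
psnet stats --input cohort.tsv --subgroup depressive

# ERGM fits (step 1: uniform occupation homophily; step 2: differential)
psnet ergm --input cohort.tsv --subgroup all --step 2

# everything at once (omit --input to simulate internally)
psnet run --seed 42 --iterations 100 --nsim 100 --out results/
```

Visit tables are UTF-8 tab-separated text with a header; the code columns
hold semicolon-separated lists. Networks are written as GraphML (node
attributes `occupation`, `municipality`; edge attribute `shared_patients`)
and as tab-separated edge lists.

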