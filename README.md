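# mmpibn — dual Gaussian Bayesian networks for MMPI-2 profiles

`mmpibn` models the dependence structure of the 13 standard MMPI-2 validity
and clinical scales (L, F, K, Hs, D, Hy, Pd, Mf, Pa, Pt, Sc, Ma, Si)
separately for healthy individuals and patients with schizophrenia, and uses
the *pair* of fitted networks as a generative classifier.  The underlying
idea: the two populations differ not only in scale elevations but in how the
scales relate to each other, so two group-specific networks carry
information a single discriminative model on a few scales does not.

The pipeline mirrors a case-control study design end to end:

1. **Cohort matching** — patients are matched 1:1 to healthy controls by
   propensity score (logistic model on age, gender, education, marital
   status; greedy nearest-neighbour matching on the logit with a 0.2-SD
   caliper), with standardized-mean-difference balance reporting.
2. **Structure learning** — one linear-Gaussian Bayesian network per group,
   learned with a hybrid algorithm: Fisher-z partial-correlation tests build
   an undirected skeleton (grow-shrink neighbour discovery, AND rule), then
   a BIC hill-climb searches DAGs restricted to that skeleton.
3. **Classification** — a profile x is scored by the log likelihood ratio
   `log p(x | healthy net) − log p(x | schizophrenia net) + log prior odds`;
   evaluation uses repeated stratified 80/20 shuffle splits with structure
   re-learned inside every split, reporting accuracy, F1 (schizophrenia
   positive) and rank-based AUC, alongside a logistic baseline on clinical
   scales 2, 7 and 8 (D, Pt, Sc).
4. **Correlation comparison** — group-wise Pearson matrices and a
   label-permutation test of their global equality (Frobenius norm of the
   off-diagonal difference).
5. **What-if imputation** — clamping any subset of scales yields an exact
   Gaussian conditional (Schur complement); the scale-2/7/8 contrast imputes
   each of D, Pt, Sc from the others under both networks on identical draws.

The clinical cohort this design is modelled on is not publicly deposited,
so the package ships a calibrated synthetic generator
(`mmpibn.simulate.mmpi2_preset`): a pair of 13-node networks whose marginal
T-score means/SDs and key correlation contrasts match published group-level
statistics, embedded in a two-group study generator with demographics and an
optional confounding age shift.  All analyses, tests and acceptance checks
run on this generator; see `docs/methods.md` for exactly what that does and
does not establish.

## Worked example

The numbered scripts under `analysis/` run the full study on synthetic data
(arguments shown are the ones used to produce this output):

```text
$ python analysis/01_simulate_cohort.py --out-dir results --seed 1
wrote 3849 rows to results/cohort.csv (714 patients)

$ python analysis/02_match_cohort.py --out-dir results
matched 714 pairs; age SMD 0.400 -> -0.003

$ python analysis/03_learn_networks.py --out-dir results
healthy: 12 arcs
schizophrenia: 8 arcs

$ python analysis/04_evaluate_classifier.py --out-dir results --iterations 10
dual network: accuracy 0.854 F1 0.856 AUC 0.926
scale-278 logistic: accuracy 0.583 AUC 0.624

$ python analysis/05_compare_correlations.py --out-dir results --n-perm 999
Frobenius statistic 1.9684, p = 0.001 (999 permutations)

$ python analysis/06_whatif_imputation.py --out-dir results
clamped target   mean     sd  p_value    n
      D      D 53.763 10.643      NaN 1000
      D     Pt  2.077  6.510    0.000 1000
      D     Sc -2.965  3.739    0.000 1000
     Pt     Pt 54.346 10.068      NaN 1000
     Pt      D -1.128  8.027    0.000 1000
     Pt     Sc -4.153  0.176    0.000 1000
     Sc     Sc 58.245 11.344      NaN 1000
     Sc      D  2.278  4.880    0.000 1000
     Sc     Pt  4.450  1.636    0.000 1000
```

The dual-network classifier beats the scale-2/7/8 logistic baseline by a
wide margin on this generator because the group difference lives mostly in
the dependence structure, not in the three scales' means.

The same pipeline is available as a CLI:

```bash
mmpibn run-all --seed 1 --out-dir results
mmpibn simulate --n-per-group 714 --seed 1 --out cohort.csv
mmpibn learn --input cohort.csv --group 0 --out net.json --graphml net.graphml
mmpibn evaluate --input cohort.csv --iterations 100 --seed 1 --out eval.json
mmpibn classify --model results/model.json --input profiles.csv --out scored.csv
mmpibn compare-correlations --input cohort.csv --n-perm 10000 --seed 1 --out corr.json
mmpibn whatif --model results/model.json --n 1000 --seed 1 --out whatif.csv
```

## Library layout

| Module | Contents |
| --- | --- |
| `mmpibn.gbn` | DAGs, linear-Gaussian CPDs, fitting, densities, BIC, MVN joint, JSON/GraphML/DOT export |
| `mmpibn.structure` | Fisher-z CI tests, skeleton discovery, BIC hill-climb, `learn_structure` |
| `mmpibn.graph_metrics` | CPDAG conversion, structural Hamming distance, skeleton F1, DAG enumeration |
| `mmpibn.matching` | Propensity estimation, greedy 1:1 caliper matching, SMD balance |
| `mmpibn.classifier` | Dual-network likelihood-ratio classifier, shuffle-split evaluation, logistic baseline |
| `mmpibn.correlations` | Pearson matrices, permutation equality test |
| `mmpibn.whatif` | Conditional distributions, clamped sampling, paired what-if tables |
| `mmpibn.simulate` | Random networks, ancestral sampling, the calibrated `mmpi2_preset`, two-group study generator |
| `mmpibn.io` / `mmpibn.cli` | Cohort CSV and model JSON I/O, pipeline, `mmpibn` command |

## Tests and reproduction

```bash
pytest -o addopts= -q            # unit + acceptance suites
python scripts/acceptance.py --seed 1 --out acceptance.json
```

The acceptance script runs the full synthetic study (714 patients, a
3,135-control candidate pool, +5-year confounding age shift, 25 evaluation
iterations) and writes its headline quantities as JSON.

One acceptance test fails by design:
`tests/test_acceptance.py::test_05_hill_climb_matches_enumeration_on_small_instances`
asserts that greedy hill-climbing attains the exhaustively enumerated BIC
optimum on *all* random 3-node problems, which the pinned search design
(empty-graph start, single best strictly-improving move, deterministic
lexicographic tie-break, no restarts) provably cannot achieve on pure
colliders whose collision node sorts first.  The mechanism is pinned by a
dedicated unit test and analysed in `docs/methods.md` ("Limitations"); the
assertion is kept as stated rather than weakened around the known failure.
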