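# ersubgroups

Stratification of ER+ (estrogen receptor alpha positive) breast tumors into
molecular subgroups from **estrogen-independent gene expression**, with the
full downstream analysis: subgroup discovery, a reusable subgroup
classifier, molecular subtyping, and subgroup survival comparison.

ER+ tumors are conventionally split into luminal A/B subtypes, but much of
their heterogeneity is independent of estrogen signaling. The idea
implemented here: use tumors profiled *before and after* estrogen
deprivation to find genes whose expression is stable within a tumor under
treatment yet variable between tumors — estrogen-independent genes — and
cluster ER+ cohorts on those genes alone.

The pipeline's stages, each exposed as library functions and as CLI
subcommands:

1. **b/w scoring** — for each gene, the ratio of between-tumor variation
   (variance of pre/post pair means, `b`) to within-pair variation
   (`w = mean((pre − post)²)/2`); the top 1,000 genes form the
   treatment-invariant panel.
2. **Class discovery** — consensus non-negative matrix factorization on the
   panel (KL-divergence multiplicative updates, restarts plus sample
   resampling), with the number of subgroups `k` chosen by the cophenetic
   coefficient of the consensus matrix over k = 2–10.
3. **Subgroup classifier** — nearest shrunken centroids trained on the
   discovery labels; the top 50 markers per subgroup form the classifier
   panel; external cohorts are standardized per feature, merged on shared
   genes, and classified with posterior probabilities (calls with posterior
   > 80% are flagged confident).
4. **Molecular subtyping** — nearest-centroid assignment by Pearson
   correlation against a user-supplied subtype centroid table.
5. **Survival** — Kaplan–Meier curves per subgroup at a 10-year horizon,
   k-group log-rank tests, O/E (Mantel–Haenszel) hazard ratios, and a
   5-year landmark comparison of treated vs untreated patients.

A seeded synthetic-cohort generator (`ersubgroups.simulate`) produces
paired pre/post cohorts and subgrouped cohorts with planted truth
(invariant genes, subgroup labels, subgroup-dependent survival), so the
whole pipeline is testable end-to-end without downloads. See
`docs/methods.md` for models, estimators, and defaults.

## Worked example

The `analysis/` scripts run the two study workflows on a synthetic bundle
(fixed seed) and write their tables under `results/`:

```bash
python analysis/01_simulate_cohorts.py
python analysis/02_invariant_genes.py
python analysis/03_class_discovery.py
python analysis/04_classifier.py
python analysis/05_survival_analysis.py
```

Output (seed 20140871):

```
scored 10000 genes over 58 tumor pairs
top-1000 panel recovers 100.0% of the 1,000 planted invariant genes

200 of the 1000 panel genes are measured in the discovery cohort (240 tumors)
cophenetic coefficients by rank: {2: 0.9314, 3: 0.9622, 4: 0.9838, 5: 0.9917, 6: 1.0, 7: 0.9997, 8: 0.9996}
selected k = 6; adjusted Rand index vs planted subgroups: 1.000

marker panel: 126 genes across 6 subgroups
reclassification concordance with NMF labels: 100.0%
validation cohort: 240 tumors classified, 100.0% with posterior > 80%

10-year event-free fraction by predicted subgroup:
  subgroup 4: 52% (n=40, events=19)
  ...
  subgroup 5: 90% (n=40, events=4)
omnibus log-rank: chi2 = 23.21, df = 5, p = 0.00031
```

The paired cohort plants 1,000 treatment-invariant genes among 10,000; the
b/w ranking recovers all of them. The discovery cohort plants 6 subgroups;
the cophenetic coefficient peaks (at exactly 1.0 — every consensus run
reproduces the same partition) at k = 6, and the consensus labels match the
planted subgroups perfectly. A shrunken-centroid classifier trained on
those labels reclassifies the discovery samples with full concordance and
confidently assigns the held-out validation cohort, whose predicted
subgroups then separate in 10-year survival exactly as planted (the
worst-outcome subgroup at 52% event-free, the best at 90%).

The same stages are scriptable on real tab-delimited cohorts via the CLI:

```bash
ersubgroups simulate --kind paired --seed 1 --out-prefix data/paired
ersubgroups bw-score --expression data/paired_expression.tsv \
    --design data/paired_design.tsv \
    --scores-out results/bw.tsv --panel-out results/panel.tsv
ersubgroups discover ... ; ersubgroups train ... ; ersubgroups classify ...
ersubgroups survival ... ; ersubgroups run-all ...
```

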