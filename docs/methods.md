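# Methods

`ersubgroups` implements a complete workflow for stratifying ER+ (estrogen
receptor alpha positive) breast tumors into molecular subgroups using genes
whose expression is *independent of estrogen signaling*, and for testing
whether those subgroups differ clinically. This note documents the models,
the estimators, the defaults, and the design choices, in that order of the
pipeline's stages.

## 1. Treatment-invariant gene discovery (b/w scoring)

**Design.** Tumors biopsied before and after estrogen deprivation (an
aromatase inhibitor in post-menopausal patients) give one pre/post
expression pair per tumor. A gene that tracks estrogen signaling changes
within a pair; a gene reflecting stable, tumor-intrinsic biology varies
*between* tumors but not *within* a pair.

**Estimator.** For each gene, with pairs $(x^{pre}_t, x^{post}_t)$ over
tumors $t = 1..T$:

- between-tumor variation $b$ = sample variance (over tumors, $n-1$
  denominator) of the pair means $(x^{pre}_t + x^{post}_t)/2$;
- within-pair variation $w$ = mean over tumors of the per-pair variance of
  the two observations, which reduces to
  $\frac{1}{T}\sum_t (x^{pre}_t - x^{post}_t)^2 / 2$;
- score = $b/w$.

This is a one-way paired variance decomposition; pair means capture stable
between-tumor differences while the half-squared difference isolates the
treatment response plus residual noise. Degenerate genes use sentinels:
$w=0,\,b>0$ scores $+\infty$ (perfectly invariant yet variable — the ideal
case, ranked first, ordered among themselves by $b$ descending);
$b=0$ scores 0 and ranks last. Finite ties break lexicographically by
feature ID. Scores are computed on the loaded (unstandardized) scale:
z-scoring every feature would erase the per-gene meaning of the ratio's
components, although the ratio itself is scale-equivariant ($b$ and $w$
both scale as $c^2$).

The panel is the top 1,000 genes by score, the study's stated panel size.
An alternative reading computes $b$ from pre-treatment samples only; the
pair-means choice is isolated in `compute_bw_scores` for substitution.

## 2. Class discovery (consensus NMF, cophenetic rank selection)

**Model.** Non-negative matrix factorization $V \approx WH$ with
$W \ge 0$ (features x k metagenes) and $H \ge 0$ (k x samples), fitted by
the classical multiplicative updates for the generalized Kullback–Leibler
divergence $D(V\|WH)$. The updates decrease the objective monotonically;
iteration stops when the relative decrease over a 10-iteration window falls
below `tol` (default 1e-6) or at `max_iter` (default 2000). W columns are
scaled to unit sum (compensated in H) so metagene magnitude lives in H.
Each sample is assigned to the metagene with the largest H entry (ties to
the lowest index).

**Input encoding.** Class discovery runs on the *folded standardized*
matrix: each panel gene is z-scored across samples, then split into a
positive and a negative half-feature (`max(x,0)` stacked over `max(-x,0)`),
restoring non-negativity in a parts-based encoding. The alternative — raw
non-negative intensities — leaves a large baseline component shared by all
samples that dominates every metagene; empirically this lets spuriously
stable over-clusterings (e.g. a single outlier sample earning its own
metagene) match the true rank's cophenetic stability, defeating rank
selection. After folding, the true rank routinely attains perfect restart
stability ($\rho = 1$ exactly) while larger ranks remain strictly below it,
which makes the argmax selection rule robust.

**Consensus.** For each candidate rank $k$ (default 2–10), `n_runs`
(default 50) factorizations are run, each perturbed by a random restart and
a random subsample of 80% of the samples; co-assignment indicators are
accumulated and normalized by co-occurrence counts into the consensus
matrix $C_k \in [0,1]$. Plain restarts alone proved insufficient: a split
fitted to the single realized noise matrix is reproduced by every restart,
so over-clusterings can look perfectly stable; resampling perturbs the
data each run, which only genuinely redundant (true) structure survives.
Per-run seeds derive deterministically from the master seed via
`SeedSequence([seed, k, run])`, so a full consensus is bit-reproducible.

**Rank selection.** $\rho_k$ is the cophenetic correlation between the
consensus dissimilarities $1 - C_k$ and the tree distances of their
average-linkage clustering; near 1 means the consensus is effectively
binary (block-stable). The selected rank maximizes $\rho_k$, ties to the
smallest $k$; a degenerate consensus (all dissimilarities equal) has no
defined $\rho$ and is skipped. Final subgroup labels cut the tree at the
selected rank.

## 3. Subgroup classifier (nearest shrunken centroids)

The standard shrunken-centroid model: standardized class-vs-overall
centroid contrasts $d_{ik} = (\bar x_{ik} - \bar x_i)/(m_k (s_i + s_0))$
with $m_k = \sqrt{1/n_k - 1/n}$, pooled within-class SD $s_i$
($n - K$ denominator), and offset $s_0$ = median of $s_i$; soft-threshold
$d'_{ik} = \mathrm{sign}(d_{ik})\max(0, |d_{ik}| - \Delta)$; shrunken
centroids reconstructed from $d'$. Classification uses
$\delta_k(x) = \sum_i (x_i - \bar x'_{ik})^2/(s_i+s_0)^2 - 2\log\pi_k$
with class-frequency priors (uniform available), posteriors
$\propto e^{-\delta_k/2}$ computed with a stable softmax, and a *confident*
flag when the top posterior exceeds 0.80 — the study's confidence rule.

Markers are the top 50 features per subgroup by $|d'_{ik}|$ at the training
$\Delta$ (ties by feature ID); with 6 subgroups and disjoint lists this is
the 300-feature classifier panel. The pipeline retrains the model on the
marker panel before classifying external cohorts (the alternative,
thresholding the full model, is available by flag). $\Delta$ can be chosen
by stratified cross-validation with the one-standard-error rule (largest
$\Delta$ within one SE of the minimum CV error), favouring smaller panels.
The model is trained on the standardized discovery matrix so that
standardized validation cohorts are scored in the same units. At
classification time up to 10% of model features may be absent (cross-
platform panels never match exactly); missing terms drop from $\delta_k$
symmetrically across classes. Singleton consensus clusters (one sample)
cannot support a centroid and are excluded from classifier training with a
warning.

## 4. Molecular subtyping (nearest centroid, Pearson)

Samples are assigned to the nearest centroid of a user-provided
features x subtypes table by Pearson correlation over the shared features
(at least 3 required; the study had 43 of the 50 subtype genes on its
discovery platform). Pearson correlation makes the assignment invariant to
per-sample affine rescaling with positive slope. Zero-variance samples are
flagged unassignable; exact correlation ties keep the first subtype in
column order and are flagged. The published centroid table is external
supplementary data and is **not** shipped; tests use synthetic centroids.
An optional flag z-scores shared features first (per-feature preprocessing
is the only preprocessing that can matter under Pearson).

## 5. Survival analysis

Endpoints are years to event (DFS or DMFS) with 0/1 indicators, truncated
administratively at 10 years (later events recoded as censored at the
horizon). Kaplan–Meier estimation is delegated to lifelines. The k-group
log-rank test and the hazard ratio are built on an explicit risk-set
tabulation (tied events share a risk set): observed and expected events per
group, hypergeometric covariance, chi-square statistic with $k-1$ degrees
of freedom. The hazard ratio is the Mantel–Haenszel/Peto estimate
$\mathrm{HR} = (O_a/E_a)/(O_b/E_b)$ with log-scale CI from
$\mathrm{Var}(\log \mathrm{HR}) \approx 1/E_a + 1/E_b$ — fully specified by
the O/E decomposition, no iterative fitting; a Cox fit could differ
slightly on real data.

**Landmark analysis.** Follow-up splits at 5 years: the pre-period censors
everyone still event-free at the landmark; the post-period conditions on
being at risk at the landmark with the clock reset. Comparing
endocrine-treated vs untreated strata per period distinguishes a
treatment effect confined to the treatment years (pre-period HR << 1,
post-period HR ≈ 1) from a uniform effect — the pattern of interest for
relapse after endocrine therapy ends.

## 6. Synthetic cohorts

Two generators provide ground-truthed inputs with exactly the structure the
stages assume. Expression is Gaussian on the log2 scale around a baseline
of 7 (post-RMA-like intensities); survival is exponential per subgroup with
administrative censoring. What they deliberately do **not** model: probe-
level artifacts, batch effects, library-size variation, heavy-tailed or
correlated noise, copy-number/mutation structure, and non-proportional
hazards beyond the piecewise constructions used in tests. Passing tests
therefore demonstrate the *estimators* recover planted structure under
clean conditions, not that real cohorts satisfy those conditions.

**Paired cohort defaults** (the study's paired design at desk scale):
58 tumors; 10,000 genes — 1,000 invariant (tumor baseline ~ N(0, 2²),
identical pre/post), 4,000 treatment-responsive (per-gene pre-to-post shift
~ N(0, 2²) common to all tumors), 5,000 pure noise; residual SD 0.5.

**Subgrouped cohort defaults:** 262 samples (the discovery cohort size) in
6 balanced subgroups (round-robin assignment, seeded shuffle); 50 signature
genes per subgroup shifted by +2 for members, 200 unstructured genes,
noise SD 1; per-subgroup exponential survival scales
(20, 60, 35, 14, 78, 55 years) chosen so 10-year event-free fractions span
roughly 50–90% — the spread between the best and worst reported subgroups —
with the worst-outcome group 4th and censoring at 10 years;
treated fraction 0.5. The stability experiments use a reduced size
(40 samples/group, 20 signature genes per group, 80 noise genes) so the
full consensus sweep stays desk-scale; recovery behavior at that size is
what the acceptance checks certify.

## 7. Numerical conventions and degenerate inputs

- SDs use the $n-1$ (sample) convention throughout; standardization of a
  constant feature yields 0 with a flag, and flagged features are excluded
  from b/w ranking.
- Missing values are rejected at load unless per-feature median imputation
  is requested; duplicate feature IDs collapse to the highest-mean row;
  duplicate sample IDs are errors.
- ER positivity from RNA-seq: ESR1 normalized count >= 250 (boundary
  inclusive).
- NMF guards divisions with 1e-12; the objective trace is checked
  non-increasing to 1e-9 slack.
- Log-rank requires at least one event; hazard ratios require at least one
  event per group; a landmark period with no events in a stratum reports
  event counts but no HR.

## 8. Known limitations

- Rank selection maximizes a coefficient that saturates near 1; it is
  reliable here because the folded encoding gives the true rank perfect
  stability, but on weaker or unbalanced structure inspecting the full
  $\rho_k$ profile (written by the pipeline) is advisable.
- The O/E hazard ratio is biased toward 1 relative to Cox under heavy
  censoring imbalance; it is used for its exact specifiability.
- Cross-platform probe mapping is out of scope: cohorts are merged on
  shared feature IDs as given.
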