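"""Desk-scale validation experiments for the pipeline.

Each function runs one property-style experiment at the study conditions —
oracle agreement on random instances, planted-truth recovery, stability of
rank selection, classifier concordance, calibration of the survival
statistics — and returns the measured quantities.  They are what the
acceptance script reports and what the acceptance test suite asserts on.

Brute-force oracles here are deliberately independent reimplementations
(loops over definitions, exhaustive enumeration) of what the library
computes with vectorized or delegated code.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from .bw import compute_bw_scores, select_top_features
from .matrix import ExpressionMatrix, standardize_and_center
from .nmf import consensus_cluster, nonneg_fold, select_k, nmf_factorize
from .pam import classify, train_shrunken_centroids
from .simulate import (
    PairedCohortSpec, PairedDesign, SubtypedCohortSpec,
    generate_paired_cohort, generate_subtyped_cohort,
)
from . import survival as surv


# -- b/w scoring --------------------------------------------------------------

def bw_brute_force(values: np.ndarray, pre_idx, post_idx):
    """Per-feature b and w from the definitions, one pair at a time.

    b: sample variance across tumors of the per-pair means.
    w: mean across tumors of the per-pair sample variance of {pre, post}
    (two observations, n-1 denominator), which equals (pre - post)^2 / 2.
    """
    n_feat = values.shape[0]
    b = np.empty(n_feat)
    w = np.empty(n_feat)
    for i in range(n_feat):
        means, within = [], []
        for p, q in zip(pre_idx, post_idx):
            pair = [values[i, p], values[i, q]]
            means.append(float(np.mean(pair)))
            within.append(float(np.var(pair, ddof=1)))
        b[i] = float(np.var(means, ddof=1))
        w[i] = float(np.mean(within))
    return b, w


def bw_oracle_agreement(n_cohorts: int = 200, seed: int = 0) -> float:
    """Max |difference| between compute_bw_scores and the brute-force oracle
    over random paired cohorts (<= 20 tumors, <= 50 features)."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_cohorts):
        n_tumors = int(rng.integers(3, 21))
        n_feat = int(rng.integers(2, 51))
        values = rng.normal(5.0, 2.0, size=(n_feat, 2 * n_tumors))
        tumors = [f"T{i}" for i in range(n_tumors)]
        pre = [f"T{i}_a" for i in range(n_tumors)]
        post = [f"T{i}_b" for i in range(n_tumors)]
        m = ExpressionMatrix(pd.DataFrame(
            values, index=[f"g{j}" for j in range(n_feat)], columns=pre + post))
        design = PairedDesign(tuple(tumors), tuple(pre), tuple(post))
        table = compute_bw_scores(m, design)
        b_ref, w_ref = bw_brute_force(values, range(n_tumors),
                                      range(n_tumors, 2 * n_tumors))
        table = table.loc[[f"g{j}" for j in range(n_feat)]]
        worst = max(worst,
                    float(np.max(np.abs(table["b"].to_numpy() - b_ref))),
                    float(np.max(np.abs(table["w"].to_numpy() - w_ref))))
    return worst


def invariant_gene_recovery(n_seeds: int = 10, seed: int = 0) -> float:
    """Mean recall of planted invariant genes by top-1,000 b/w selection
    (50 tumors, 1,000 invariant among 10,000 genes, between_sd 2,
    treatment_shift_sd 2, noise_sd 0.5)."""
    recalls = []
    for s in range(n_seeds):
        spec = PairedCohortSpec(n_tumors=50, n_invariant_genes=1000,
                                n_responsive_genes=4000, n_noise_genes=5000,
                                between_sd=2.0, treatment_shift_sd=2.0,
                                noise_sd=0.5, seed=seed + s)
        expr, design, truth = generate_paired_cohort(spec)
        panel = select_top_features(compute_bw_scores(expr, design), 1000)
        recalls.append(float(np.mean(truth.loc[panel] == "invariant")))
    return float(np.mean(recalls))


# -- consensus NMF ------------------------------------------------------------

#: Reduced-size class-discovery conditions used for stability experiments:
#: 40 samples per planted subgroup, 20 signature genes per subgroup plus 80
#: unstructured genes, effect 2 over noise SD 1.
RANK_SELECTION_SIZES = dict(n_per_group=40, n_signature_genes_per_group=20,
                            n_noise_genes=80, signature_effect=2.0, noise_sd=1.0)


def _subtyped_spec(k_true: int, seed: int, **overrides) -> SubtypedCohortSpec:
    sizes = {**RANK_SELECTION_SIZES, **overrides}
    n_per_group = sizes.pop("n_per_group")
    scales = tuple(SubtypedCohortSpec.survival_scales_years)[:k_true]
    if len(scales) < k_true:
        scales = tuple(20.0 + 10.0 * i for i in range(k_true))
    return SubtypedCohortSpec(n_samples=n_per_group * k_true, k_true=k_true,
                              survival_scales_years=scales, seed=seed, **sizes)


def rank_selection_recovery(k_true: int, n_seeds: int = 10, seed: int = 0,
                            k_range=range(2, 9), n_runs: int = 30,
                            max_iter: int = 500, tol: float = 1e-6):
    """Fraction of seeds where consensus NMF selects the planted rank and
    recovers the planted labels with adjusted Rand index >= 0.9."""
    hits, selected, aris = 0, [], []
    for s in range(n_seeds):
        expr, labels, _ = generate_subtyped_cohort(_subtyped_spec(k_true, seed + s))
        V = nonneg_fold(standardize_and_center(expr).values)
        res = consensus_cluster(V, k_range=k_range, n_runs=n_runs,
                                seed=seed + s, max_iter=max_iter, tol=tol)
        k_hat = select_k(res)
        ari = float(adjusted_rand_score(labels.to_numpy(), res.labels[k_true]))
        hits += int(k_hat == k_true and ari >= 0.9)
        selected.append(k_hat)
        aris.append(ari)
    return {"hit_fraction": hits / n_seeds, "selected": selected, "ari": aris}


def nmf_monotonicity(n_instances: int = 100, seed: int = 0):
    """Objective-trace monotonicity on random instances, and the divergence
    reached on exact rank-k products relative to the rank-1 mean baseline."""
    rng = np.random.default_rng(seed)
    max_increase = 0.0
    for i in range(n_instances):
        shape = (int(rng.integers(8, 25)), int(rng.integers(6, 20)))
        V = rng.gamma(2.0, 1.0, size=shape)
        k = int(rng.integers(2, min(shape) - 1)) if min(shape) > 3 else 2
        f = nmf_factorize(V, k, seed=int(rng.integers(2**31)), max_iter=150)
        diffs = np.diff(f.objective_trace)
        if diffs.size:
            max_increase = max(max_increase, float(diffs.max()))

    worst_rel = 0.0
    for i in range(10):
        W0 = rng.gamma(2.0, 1.0, size=(20, 3))
        H0 = rng.gamma(2.0, 1.0, size=(3, 15))
        V = W0 @ H0
        f = nmf_factorize(V, 3, seed=int(rng.integers(2**31)),
                          max_iter=5000, tol=0.0)
        from .nmf import kl_divergence
        baseline = kl_divergence(V, np.full_like(V, V.mean()))
        worst_rel = max(worst_rel, f.objective_trace[-1] / baseline)
    return {"max_trace_increase": max_increase, "exact_rank_rel_divergence": worst_rel}


# -- shrunken centroids -------------------------------------------------------

def nearest_centroid_oracle_agreement(n_instances: int = 100, seed: int = 0) -> float:
    """Fraction of samples where the reduced discriminant (no shrinkage,
    unit dispersions, equal priors) matches brute-force Euclidean
    nearest-centroid assignment."""
    rng = np.random.default_rng(seed)
    agree, total = 0, 0
    for _ in range(n_instances):
        n_feat = int(rng.integers(3, 15))
        n_classes = int(rng.integers(2, 5))
        n_per = int(rng.integers(3, 8))
        X = rng.normal(size=(n_feat, n_classes * n_per))
        y = np.repeat([f"c{j}" for j in range(n_classes)], n_per)
        df = pd.DataFrame(X, index=[f"g{i}" for i in range(n_feat)],
                          columns=[f"s{i}" for i in range(X.shape[1])])
        model = train_shrunken_centroids(df, y, delta=0.0, priors="uniform")
        # reduced case: unit dispersions, no offset
        model.pooled_sd = np.ones(n_feat)
        model.s0 = 0.0
        res = classify(model, df)
        cent = model.class_centroids
        for i in range(X.shape[1]):
            dists = [float(np.sum((X[:, i] - cent[:, j]) ** 2))
                     for j in range(n_classes)]
            oracle = model.classes[int(np.argmin(dists))]
            agree += int(res.predicted[i] == oracle)
            total += 1
    return agree / total


def classifier_nmf_concordance(seed: int = 0, n_runs: int = 30,
                               max_iter: int = 500) -> float:
    """Concordance between consensus-NMF subgroup labels and reclassification
    of the same samples by a shrunken-centroid model trained on those labels
    (6-subgroup synthetic cohort)."""
    expr, _, _ = generate_subtyped_cohort(_subtyped_spec(6, seed))
    train = standardize_and_center(expr)
    res = consensus_cluster(nonneg_fold(train.values), k_range=(6,),
                            n_runs=n_runs, seed=seed, max_iter=max_iter, tol=1e-6)
    labels = pd.Series(res.labels[6], index=expr.sample_ids)
    model = train_shrunken_centroids(train, labels)
    out = classify(model, train)
    return float(np.mean(out.predicted == labels.to_numpy()))


# -- survival -----------------------------------------------------------------

def logrank_type1_error(n_reps: int = 2000, n_per_group: int = 100,
                        seed: int = 0, alpha: float = 0.05) -> float:
    """Empirical rejection rate of the two-group log-rank test under the null
    (both groups exponential with the same scale, no censoring)."""
    rng = np.random.default_rng(seed)
    groups = np.array([0] * n_per_group + [1] * n_per_group)
    events = np.ones(2 * n_per_group, dtype=int)
    rejections = 0
    for _ in range(n_reps):
        times = rng.exponential(10.0, size=2 * n_per_group)
        res = surv.logrank_test(times, events, groups)
        rejections += int(res.p_value <= alpha)
    return rejections / n_reps


def hr_recovery(true_hr: float = 0.5, n_per_group: int = 500,
                n_reps: int = 20, seed: int = 0) -> float:
    """Mean O/E hazard-ratio estimate over replicates of two exponential
    groups with the given true hazard ratio, no censoring."""
    rng = np.random.default_rng(seed)
    estimates = []
    for _ in range(n_reps):
        ta = rng.exponential(1.0 / true_hr, size=n_per_group)  # hazard = true_hr
        tb = rng.exponential(1.0, size=n_per_group)            # hazard = 1
        ea = eb = np.ones(n_per_group, dtype=int)
        estimates.append(surv.hazard_ratio(ta, ea, tb, eb).hr)
    return float(np.mean(estimates))


def landmark_separation(n_reps: int = 500, n_per_arm: int = 150,
                        landmark: float = 5.0, seed: int = 0) -> float:
    """Fraction of replicates where the pre-landmark HR is below the
    post-landmark HR when treatment suppresses the hazard only before the
    landmark (treated pre-landmark hazard = 0.25 x untreated; identical
    hazards after)."""
    rng = np.random.default_rng(seed)
    base_hazard = 0.15  # per year, untreated
    horizon = 10.0
    count, used = 0, 0
    for _ in range(n_reps):
        # piecewise-exponential times: treated arm has hazard/4 before landmark
        t_treat = _piecewise_exp_times(rng, n_per_arm, base_hazard / 4.0,
                                       base_hazard, landmark)
        t_ctrl = _piecewise_exp_times(rng, n_per_arm, base_hazard,
                                      base_hazard, landmark)
        times = np.concatenate([t_treat, t_ctrl])
        events = (times <= horizon).astype(int)
        times = np.minimum(times, horizon)
        strata = np.array([1] * n_per_arm + [0] * n_per_arm)
        res = surv.landmark_compare(times, events, strata, landmark=landmark)
        if res.pre is None or res.post is None:
            continue
        used += 1
        count += int(res.pre.hr < res.post.hr)
    return count / used if used else float("nan")


def _piecewise_exp_times(rng, n, hazard_early, hazard_late, breakpoint):
    """Event times with hazard `hazard_early` before the breakpoint and
    `hazard_late` after (inverse-CDF sampling)."""
    u = rng.random(n)
    cum_break = hazard_early * breakpoint
    target = -np.log(1.0 - u)
    early = target <= cum_break
    times = np.where(early, target / hazard_early,
                     breakpoint + (target - cum_break) / hazard_late)
    return times
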