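"""Nearest-shrunken-centroid classification and subgroup marker extraction.

The model standardizes each feature's class-centroid deviation from the
overall centroid,

    d_ik = (xbar_ik - xbar_i) / (m_k * (s_i + s0)),   m_k = sqrt(1/n_k - 1/n),

where s_i is the pooled within-class SD and s0 (the median of the s_i)
guards against near-zero-variance features.  Soft-thresholding by Delta,

    d'_ik = sign(d_ik) * max(0, |d_ik| - Delta),

shrinks most features to exactly zero and yields shrunken centroids

    xbar'_ik = xbar_i + m_k * (s_i + s0) * d'_ik.

Classification scores a sample x by the discriminant

    delta_k(x) = sum_i (x_i - xbar'_ik)^2 / (s_i + s0)^2 - 2 log pi_k,

assigns argmin, and converts discriminants to posterior probabilities
softmax(-delta/2).  A call is *confident* when the maximum posterior
exceeds a threshold (default 0.80).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .matrix import ExpressionMatrix


@dataclass
class ShrunkenCentroidModel:
    feature_ids: list
    classes: list
    overall_centroid: np.ndarray      # (features,)
    class_centroids: np.ndarray       # features x classes (unshrunken means)
    pooled_sd: np.ndarray             # s_i, (features,)
    s0: float
    mk: np.ndarray                    # (classes,)
    priors: np.ndarray                # (classes,), sums to 1
    delta: float
    d: np.ndarray                     # standardized differences d_ik
    d_shrunk: np.ndarray              # d'_ik after soft-thresholding
    shrunken_centroids: np.ndarray    # xbar'_ik, features x classes

    @property
    def active_features(self) -> np.ndarray:
        """Boolean mask of features with any nonzero shrunken difference."""
        return np.any(self.d_shrunk != 0.0, axis=1)


def _as_frame(X) -> pd.DataFrame:
    return X.data if isinstance(X, ExpressionMatrix) else pd.DataFrame(X)


def train_shrunken_centroids(X, labels, delta: float = 0.0,
                             priors: str | dict = "frequency") -> ShrunkenCentroidModel:
    """Fit the shrunken-centroid model.

    Parameters
    ----------
    X : ExpressionMatrix or DataFrame
        Features x samples.
    labels : array-like
        Class label per sample (aligned with X's columns; a pandas Series is
        aligned by sample ID).
    delta : float
        Soft-threshold amount (>= 0).  ``delta=0`` reproduces the per-class
        means exactly.
    priors : 'frequency' | 'uniform' | dict
        Class priors; default is observed class frequencies.
    """
    if delta < 0:
        raise ValueError("delta must be >= 0")
    df = _as_frame(X)
    if isinstance(labels, pd.Series):
        labels = labels.reindex(df.columns)
        if labels.isna().any():
            raise ValueError("labels missing for some samples")
    y = np.asarray(labels)
    if len(y) != df.shape[1]:
        raise ValueError("one label per sample required")

    classes = sorted(pd.unique(y).tolist())
    if len(classes) < 2:
        raise ValueError("need >= 2 classes")
    counts = {c: int((y == c).sum()) for c in classes}
    small = [c for c, n in counts.items() if n < 2]
    if small:
        raise ValueError(f"classes with < 2 samples: {small}")

    V = df.to_numpy(dtype=float)
    n = V.shape[1]
    n_k = np.array([counts[c] for c in classes], dtype=float)

    overall = V.mean(axis=1)
    cent = np.column_stack([V[:, y == c].mean(axis=1) for c in classes])

    # pooled within-class variance with n - K degrees of freedom
    ss = np.zeros(V.shape[0])
    for j, c in enumerate(classes):
        ss += ((V[:, y == c] - cent[:, [j]]) ** 2).sum(axis=1)
    s = np.sqrt(ss / (n - len(classes)))
    s0 = float(np.median(s))

    mk = np.sqrt(1.0 / n_k - 1.0 / n)
    denom = (mk[None, :] * (s + s0)[:, None])
    d = (cent - overall[:, None]) / denom
    d_shrunk = np.sign(d) * np.maximum(0.0, np.abs(d) - delta)
    shrunk_cent = overall[:, None] + denom * d_shrunk

    if priors == "frequency":
        pi = n_k / n
    elif priors == "uniform":
        pi = np.full(len(classes), 1.0 / len(classes))
    else:
        pi = np.array([priors[c] for c in classes], dtype=float)
        pi = pi / pi.sum()

    return ShrunkenCentroidModel(
        feature_ids=list(df.index), classes=classes, overall_centroid=overall,
        class_centroids=cent, pooled_sd=s, s0=s0, mk=mk, priors=pi, delta=delta,
        d=d, d_shrunk=d_shrunk, shrunken_centroids=shrunk_cent,
    )


def select_subgroup_markers(model: ShrunkenCentroidModel,
                            n_per_class: int = 50) -> pd.DataFrame:
    """Top ``n_per_class`` features per class by |d'_ik| (ties by feature ID).

    Returns a DataFrame indexed by the union of per-class top lists, with one
    boolean column per class marking membership; its size is at most
    ``k * n_per_class`` (smaller when lists overlap).
    """
    n_features = len(model.feature_ids)
    if n_per_class > n_features:
        raise ValueError(f"n_per_class={n_per_class} exceeds {n_features} features")
    fid = np.asarray(model.feature_ids)
    membership: dict[str, set] = {}
    for j, c in enumerate(model.classes):
        mag = np.abs(model.d_shrunk[:, j])
        order = np.lexsort((fid, -mag))[:n_per_class]
        membership[c] = set(fid[order])
    panel = [f for f in model.feature_ids if any(f in s for s in membership.values())]
    out = pd.DataFrame(
        {c: [f in membership[c] for f in panel] for c in model.classes},
        index=pd.Index(panel, name="feature_id"),
    )
    return out


@dataclass
class ClassificationResult:
    sample_ids: list
    classes: list
    predicted: np.ndarray            # class label per sample
    posteriors: np.ndarray           # samples x classes, rows sum to 1
    confident: np.ndarray            # bool per sample
    threshold: float
    n_features_used: int

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame(self.posteriors,
                           index=pd.Index(self.sample_ids, name="sample_id"),
                           columns=[f"p_{c}" for c in self.classes])
        out.insert(0, "predicted_subgroup", self.predicted)
        out["confident"] = self.confident
        return out


def classify(model: ShrunkenCentroidModel, X, threshold: float = 0.80,
             max_missing_frac: float = 0.10) -> ClassificationResult:
    """Classify samples with the shrunken-centroid discriminant.

    Model features absent from ``X`` (cross-platform panels rarely match
    exactly) are dropped from the discriminant symmetrically across classes,
    up to ``max_missing_frac`` of the model's features.
    """
    df = _as_frame(X)
    present = [f for f in model.feature_ids if f in df.index]
    n_missing = len(model.feature_ids) - len(present)
    if n_missing > max_missing_frac * len(model.feature_ids):
        raise ValueError(
            f"{n_missing}/{len(model.feature_ids)} model features missing from input "
            f"(allowed fraction {max_missing_frac})"
        )
    pos = {f: i for i, f in enumerate(model.feature_ids)}
    idx = [pos[f] for f in present]
    cent = model.shrunken_centroids[idx]
    sd = (model.pooled_sd + model.s0)[idx]
    V = df.loc[present].to_numpy(dtype=float)

    # delta_k(x): squared standardized distance to each shrunken centroid
    z = (V[:, :, None] - cent[:, None, :]) / sd[:, None, None]
    disc = (z ** 2).sum(axis=0) - 2.0 * np.log(model.priors)[None, :]

    # stable softmax of -disc/2
    half = -0.5 * disc
    half -= half.max(axis=1, keepdims=True)
    post = np.exp(half)
    post /= post.sum(axis=1, keepdims=True)

    pred_idx = np.argmin(disc, axis=1)
    predicted = np.asarray(model.classes, dtype=object)[pred_idx]
    confident = post.max(axis=1) > threshold
    return ClassificationResult(
        sample_ids=list(df.columns), classes=list(model.classes),
        predicted=predicted, posteriors=post, confident=confident,
        threshold=threshold, n_features_used=len(present),
    )


def cross_validate_threshold(X, labels, delta_grid, folds: int = 5,
                             seed: int = 0, priors: str | dict = "frequency"):
    """Stratified-CV choice of the shrinkage threshold Delta.

    Returns ``(delta_star, table)`` where the table lists the CV error per
    Delta.  The chosen Delta is the largest one whose error is within one
    standard error (across folds) of the minimum error — the usual
    parsimony rule, favouring smaller marker panels.
    """
    df = _as_frame(X)
    if isinstance(labels, pd.Series):
        labels = labels.reindex(df.columns)
    y = np.asarray(labels)
    if folds < 2:
        raise ValueError("folds must be >= 2")
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < folds:
        raise ValueError("smallest class has fewer samples than folds")

    delta_grid = sorted(float(d) for d in delta_grid)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    fold_err = np.zeros((len(delta_grid), folds))
    cols = np.arange(df.shape[1])
    for f, (tr, te) in enumerate(skf.split(cols, y)):
        for i, delta in enumerate(delta_grid):
            model = train_shrunken_centroids(df.iloc[:, tr], y[tr],
                                             delta=delta, priors=priors)
            res = classify(model, df.iloc[:, te])
            fold_err[i, f] = float(np.mean(res.predicted != y[te]))

    err = fold_err.mean(axis=1)
    se = fold_err.std(axis=1, ddof=1) / np.sqrt(folds)
    i_min = int(np.argmin(err))
    cutoff = err[i_min] + se[i_min]
    delta_star = max(d for d, e in zip(delta_grid, err) if e <= cutoff)
    table = pd.DataFrame({"delta": delta_grid, "cv_error": err, "se": se})
    return delta_star, table


# -- model (de)serialization --------------------------------------------------

def write_model(model: ShrunkenCentroidModel, path) -> None:
    """Serialize the model as a flat tab-delimited bundle."""
    header = pd.DataFrame({
        "key": ["classes", "s0", "delta", "priors", "mk"],
        "value": [",".join(map(str, model.classes)), f"{model.s0:.17g}",
                  f"{model.delta:.17g}",
                  ",".join(f"{p:.17g}" for p in model.priors),
                  ",".join(f"{m:.17g}" for m in model.mk)],
    })
    body = pd.DataFrame(
        np.column_stack([model.overall_centroid, model.pooled_sd,
                         model.class_centroids, model.shrunken_centroids]),
        index=pd.Index(model.feature_ids, name="feature_id"),
        columns=(["overall", "pooled_sd"]
                 + [f"centroid_{c}" for c in model.classes]
                 + [f"shrunken_{c}" for c in model.classes]),
    )
    with open(path, "w") as fh:
        for _, row in header.iterrows():
            fh.write(f"#{row['key']}\t{row['value']}\n")
        body.to_csv(fh, sep="\t", float_format="%.17g")


def read_model(path) -> ShrunkenCentroidModel:
    meta = {}
    n_meta = 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, value = line[1:].rstrip("\n").split("\t", 1)
            meta[key] = value
            n_meta += 1
    body = pd.read_csv(path, sep="\t", skiprows=n_meta, index_col=0)
    classes = meta["classes"].split(",")
    cent = body[[f"centroid_{c}" for c in classes]].to_numpy()
    shrunk = body[[f"shrunken_{c}" for c in classes]].to_numpy()
    s = body["pooled_sd"].to_numpy()
    overall = body["overall"].to_numpy()
    s0 = float(meta["s0"])
    delta = float(meta["delta"])
    mk = np.array([float(v) for v in meta["mk"].split(",")])
    priors = np.array([float(v) for v in meta["priors"].split(",")])
    denom = mk[None, :] * (s + s0)[:, None]
    d = (cent - overall[:, None]) / denom
    d_shrunk = (shrunk - overall[:, None]) / denom
    return ShrunkenCentroidModel(
        feature_ids=list(body.index), classes=classes, overall_centroid=overall,
        class_centroids=cent, pooled_sd=s, s0=s0, mk=mk, priors=priors,
        delta=delta, d=d, d_shrunk=d_shrunk, shrunken_centroids=shrunk,
    )
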