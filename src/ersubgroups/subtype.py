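"""Nearest-centroid molecular subtype assignment by Pearson correlation.

Each sample is correlated, over the features shared between the expression
matrix and a provided centroid table (e.g. the five intrinsic breast-cancer
subtype centroids), with every centroid; the subtype with the highest
correlation is assigned.  Pearson correlation is invariant to per-sample
affine rescaling with positive slope, so cross-platform intensity scaling
does not change assignments; only per-feature preprocessing matters.

The centroid table is an input artifact (tab-delimited, header = subtype
names, rows = feature IDs); published centroid values are external
supplementary data and are not shipped here.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix


def load_centroids(path) -> pd.DataFrame:
    """Read a features x subtypes centroid table (tab-delimited)."""
    c = pd.read_csv(path, sep="\t", index_col=0)
    if c.shape[1] < 2:
        raise ValueError("centroid table needs >= 2 subtypes")
    if c.index.has_duplicates:
        raise ValueError("duplicate feature IDs in centroid table")
    return c.astype(float)


def assign_subtype(X, centroids: pd.DataFrame, min_shared: int = 3,
                   standardize_features: bool = False) -> pd.DataFrame:
    """Assign each sample to its nearest centroid by Pearson correlation.

    Returns a DataFrame with ``subtype``, one correlation column per
    subtype (``r_<name>``), ``n_shared_features``, and flags: ``tie`` (the
    best correlation is attained by several subtypes; the first in column
    order is kept) and ``unassignable`` (zero-variance sample over the
    shared features; subtype is NA).

    ``standardize_features`` optionally z-scores each shared feature across
    samples first (a per-feature preprocessing choice; per-sample scaling is
    irrelevant under Pearson).
    """
    df = X.data if isinstance(X, ExpressionMatrix) else pd.DataFrame(X)
    shared = [f for f in centroids.index if f in df.index]
    if len(shared) < min_shared:
        raise ValueError(
            f"only {len(shared)} features shared with centroid table "
            f"(need >= {min_shared})"
        )
    V = df.loc[shared].to_numpy(dtype=float)      # shared x samples
    C = centroids.loc[shared].to_numpy(dtype=float)  # shared x subtypes
    if standardize_features:
        sd = V.std(axis=1, ddof=1, keepdims=True)
        V = (V - V.mean(axis=1, keepdims=True)) / np.where(sd == 0, 1.0, sd)

    Vc = V - V.mean(axis=0, keepdims=True)
    Cc = C - C.mean(axis=0, keepdims=True)
    v_norm = np.linalg.norm(Vc, axis=0)
    c_norm = np.linalg.norm(Cc, axis=0)
    unassignable = v_norm == 0
    if np.any(c_norm == 0):
        bad = centroids.columns[np.argwhere(c_norm == 0)[0][0]]
        raise ValueError(f"centroid {bad!r} is constant over shared features")

    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Vc.T @ Cc) / (np.where(unassignable, 1.0, v_norm)[:, None] * c_norm[None, :])
    r[unassignable] = np.nan

    names = list(centroids.columns)
    best = np.full(len(df.columns), -1)
    tie = np.zeros(len(df.columns), dtype=bool)
    for i in range(len(df.columns)):
        if unassignable[i]:
            continue
        best[i] = int(np.argmax(r[i]))
        tie[i] = int(np.sum(r[i] == r[i, best[i]])) > 1

    out = pd.DataFrame(
        {"subtype": [names[b] if b >= 0 else pd.NA for b in best]},
        index=pd.Index(df.columns, name="sample_id"),
    )
    for j, name in enumerate(names):
        out[f"r_{name}"] = r[:, j]
    out["n_shared_features"] = len(shared)
    out["tie"] = tie
    out["unassignable"] = unassignable
    return out
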