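"""Between/within (b/w) variance scoring over paired pre/post samples.

A gene that keeps its expression level within a tumor across estrogen
deprivation, while differing between tumors, is informative about the
treatment-independent biology of the tumor.  The b/w score quantifies this
per feature as a ratio of two variance components over the paired design:

* ``b`` — between-tumor variation: the sample variance (n-1 denominator)
  across tumors of the per-tumor pair means,
* ``w`` — within-pair variation: the mean over tumors of the squared
  per-pair deviation about the pair mean, i.e. mean((pre - post)^2) / 2.

``score = b / w``; high scores flag treatment-invariant, between-tumor
variable features.  Degenerate cases use sentinels: ``w == 0`` with
``b > 0`` scores +inf (perfectly invariant yet variable — the most
desirable case, ranked first, ordered among themselves by ``b``
descending); ``b == 0`` scores 0 (no between-tumor signal, ranked last).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix
from .simulate import PairedDesign


def compute_bw_scores(m: ExpressionMatrix, design: PairedDesign) -> pd.DataFrame:
    """Score every feature by its between/within variance ratio.

    Returns a DataFrame indexed by feature ID with columns ``b``, ``w``,
    ``score``, ``rank`` (1 = highest score).  Ranking order: +inf sentinel
    features first (by ``b`` descending), then finite scores descending;
    ties broken lexicographically by feature ID.
    """
    if design.n_tumors < 3:
        raise ValueError("paired design needs >= 3 tumors")
    sample_set = set(m.sample_ids)
    for t, p, q in zip(design.tumor_ids, design.pre_sample_ids, design.post_sample_ids):
        if p not in sample_set or q not in sample_set:
            raise ValueError(f"tumor {t!r}: pre or post sample missing from matrix")

    pre = m.data[list(design.pre_sample_ids)].to_numpy()
    post = m.data[list(design.post_sample_ids)].to_numpy()

    pair_means = (pre + post) / 2.0
    b = pair_means.var(axis=1, ddof=1)
    w = np.mean((pre - post) ** 2, axis=1) / 2.0

    with np.errstate(divide="ignore", invalid="ignore"):
        score = np.where(w > 0, b / np.where(w > 0, w, 1.0), np.inf)
    score = np.where(b == 0, 0.0, score)

    table = pd.DataFrame({"b": b, "w": w, "score": score}, index=pd.Index(m.feature_ids, name="feature_id"))
    # sort: score desc; within the +inf block b desc; ties by feature ID
    inf_b = np.where(np.isinf(table["score"]), table["b"], 0.0)
    order = table.assign(_inf_b=inf_b).sort_values(
        by=["score", "_inf_b", "feature_id"],
        ascending=[False, False, True],
        kind="mergesort",
    ).index
    table["rank"] = pd.Series(np.arange(1, len(table) + 1), index=order)
    return table.loc[order]


def select_top_features(table: pd.DataFrame, n: int) -> list[str]:
    """The ``n`` top-ranked features (default study panel size is 1,000).

    Features with ``score == 0`` (no between-tumor variance, or constant)
    are never selected; requesting more than the number of informative
    features is an error.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    informative = table[table["score"] > 0]
    if n > len(informative):
        raise ValueError(
            f"requested {n} features but only {len(informative)} are informative"
        )
    return informative.sort_values("rank").index[:n].tolist()


def write_score_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", float_format="%.10g")


def write_feature_panel(panel, path) -> None:
    pd.Series(panel, name="feature_id").to_csv(path, sep="\t", index=False)
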