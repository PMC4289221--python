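#!/usr/bin/env python
"""Train the shrunken-centroid subgroup classifier on the discovery-cohort
NMF labels, extract the marker panel (top 50 genes per subgroup), and
classify the independent validation cohort with the 80% confidence rule.

Reads results/cohorts/ and results/discovery/, writes results/classifier/
(model, marker panel, validation calls) and prints the NMF/classifier
concordance and the confident-call fraction.
"""

from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from ersubgroups import (
    classify, load_expression_matrix, select_subgroup_markers,
    standardize_and_center, train_shrunken_centroids,
)
from ersubgroups.pam import write_model

ROOT = Path(__file__).resolve().parents[1] / "results"
N_MARKERS_PER_SUBGROUP = 50
CONFIDENCE = 0.80


def main() -> None:
    out = ROOT / "classifier"
    out.mkdir(parents=True, exist_ok=True)

    disc = load_expression_matrix(ROOT / "cohorts" / "discovery_expression.tsv")
    labels = pd.read_csv(ROOT / "discovery" / "subgroup_labels.tsv", sep="\t",
                         index_col=0)["subgroup"]
    panel = pd.read_csv(ROOT / "bw" / "invariant_panel.tsv", sep="\t")["feature_id"]
    usable = [f for f in panel if f in disc.data.index]
    train = standardize_and_center(disc.subset_features(usable))

    model = train_shrunken_centroids(train, labels)
    markers = select_subgroup_markers(model, min(N_MARKERS_PER_SUBGROUP,
                                                 train.n_features))
    model = train_shrunken_centroids(train.subset_features(list(markers.index)),
                                     labels)
    write_model(model, out / "pam_model.tsv")
    markers.to_csv(out / "subgroup_markers.tsv", sep="\t")

    back = classify(model, train, threshold=CONFIDENCE)
    concordance = float(np.mean(back.predicted == labels.to_numpy()))
    print(f"marker panel: {len(markers)} genes across {labels.nunique()} subgroups")
    print(f"reclassification concordance with NMF labels: {100 * concordance:.1f}%")

    val = load_expression_matrix(ROOT / "cohorts" / "validation_expression.tsv")
    val_std = standardize_and_center(val)
    calls = classify(model, val_std, threshold=CONFIDENCE)
    calls.to_frame().to_csv(out / "validation_calls.tsv", sep="\t",
                            float_format="%.6g")
    confident = calls.confident.mean()
    print(f"validation cohort: {len(calls.sample_ids)} tumors classified, "
          f"{100 * confident:.1f}% with posterior > {CONFIDENCE:.0%}")

    truth = pd.read_csv(ROOT / "cohorts" / "validation_true_labels.tsv",
                        sep="\t", index_col=0)["subgroup"]
    ari = adjusted_rand_score(truth.loc[calls.sample_ids],
                              calls.predicted.astype(str))
    print(f"agreement with planted validation subgroups (ARI): {ari:.3f}")


if __name__ == "__main__":
    main()
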