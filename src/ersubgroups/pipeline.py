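"""End-to-end orchestration of the two workflows.

Discovery: paired pre/post cohort -> b/w scores -> top-N invariant-feature
panel -> consensus NMF over the discovery cohort restricted to the panel ->
rank selection -> subgroup labels -> shrunken-centroid model trained on the
labels -> marker panel (top features per subgroup).

Validation: standardize each validation cohort per feature, merge on shared
features, classify with the trained model, flag confident calls, then run
subgroup survival comparisons (10-year horizon) and the treated-vs-untreated
landmark analysis within subgroups.

Every stage writes plain tab-delimited artifacts plus a manifest (config
values, seed, package version) so any stage can be rerun in isolation and
a full run replayed bit-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .matrix import ExpressionMatrix, merge_cohorts, standardize_and_center
from .bw import compute_bw_scores, select_top_features, write_feature_panel, write_score_table
from .nmf import consensus_cluster, nonneg_fold, select_k
from .pam import classify, select_subgroup_markers, train_shrunken_centroids, write_model
from .simulate import PairedDesign
from . import survival as surv

log = logging.getLogger("ersubgroups")


@dataclass(frozen=True)
class PipelineConfig:
    """Pipeline constants; the defaults are the study's stated settings
    (1,000-feature invariant panel, ranks 2-10, 50 markers per subgroup,
    80% posterior confidence, 10-year endpoints, 5-year landmark)."""

    n_top_features: int = 1000
    k_min: int = 2
    k_max: int = 10
    n_runs: int = 50
    n_markers_per_class: int = 50
    confidence_threshold: float = 0.80
    horizon_years: float = 10.0
    landmark_years: float = 5.0
    nmf_max_iter: int = 2000
    nmf_tol: float = 1e-6
    pam_delta: float = 0.0
    retrain_on_panel: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.k_max < self.k_min or self.k_min < 2:
            raise ValueError("need 2 <= k_min <= k_max")
        if self.n_top_features <= 0 or self.n_runs < 2:
            raise ValueError("n_top_features must be > 0 and n_runs >= 2")
        if not (0 < self.confidence_threshold < 1):
            raise ValueError("confidence_threshold must be in (0, 1)")
        if self.horizon_years <= 0 or self.landmark_years <= 0:
            raise ValueError("horizon and landmark must be > 0")

    def manifest(self) -> dict:
        cfg = dataclasses.asdict(self)
        blob = json.dumps(cfg, sort_keys=True).encode()
        return {"config": cfg, "config_sha256": hashlib.sha256(blob).hexdigest(),
                "version": __version__}


def _write_manifest(outdir: Path, config: PipelineConfig, stage: str, counts: dict):
    manifest = config.manifest()
    manifest["stage"] = stage
    manifest["counts"] = counts
    (outdir / f"manifest_{stage}.json").write_text(json.dumps(manifest, indent=2))


def run_discovery(paired: ExpressionMatrix, design: PairedDesign,
                  discovery: ExpressionMatrix, config: PipelineConfig,
                  outdir=None) -> dict:
    """Discovery workflow; returns a dict of stage artifacts.

    Keys: ``scores`` (b/w table), ``panel`` (feature list), ``consensus``
    (ConsensusResult), ``k`` (selected rank), ``labels`` (sample -> subgroup
    Series), ``model`` (ShrunkenCentroidModel), ``markers`` (marker panel
    DataFrame).
    """
    scores = compute_bw_scores(paired, design)
    panel = select_top_features(scores, config.n_top_features)
    log.info("b/w scoring: %d features scored, %d selected", len(scores), len(panel))

    usable = [f for f in panel if f in discovery.data.index]
    if len(usable) < len(panel):
        log.warning("%d panel features absent from discovery cohort", len(panel) - len(usable))
    disc = discovery.subset_features(usable)
    # class discovery runs on the folded standardized matrix: per-feature
    # z-scoring removes the dominant shared baseline, and the positive/
    # negative split restores non-negativity in a parts-based encoding
    train_mat = standardize_and_center(disc) if disc.scale != "standardized" else disc
    V = nonneg_fold(train_mat.values)
    result = consensus_cluster(
        V, k_range=range(config.k_min, config.k_max + 1), n_runs=config.n_runs,
        seed=config.seed, max_iter=config.nmf_max_iter, tol=config.nmf_tol,
    )
    k = select_k(result)
    labels = pd.Series(result.labels[k], index=disc.sample_ids, name="subgroup")
    log.info("consensus NMF: selected k=%d (rho=%.3f)", k, result.cophenetic[k])

    # singleton consensus clusters cannot support a centroid model; their
    # samples are left unlabeled for classifier training
    counts = labels.value_counts()
    trainable = labels[labels.isin(counts[counts >= 2].index)]
    if len(trainable) < len(labels):
        log.warning("%d samples in singleton clusters excluded from training",
                    len(labels) - len(trainable))
    model = train_shrunken_centroids(
        train_mat.subset_samples(list(trainable.index)), trainable,
        delta=config.pam_delta)
    markers = select_subgroup_markers(model, config.n_markers_per_class)
    if config.retrain_on_panel:
        model = train_shrunken_centroids(
            train_mat.subset_features(list(markers.index)), labels,
            delta=config.pam_delta,
        )
    log.info("classifier: %d marker features across %d subgroups", len(markers), k)

    artifacts = {"scores": scores, "panel": panel, "consensus": result, "k": k,
                 "labels": labels, "model": model, "markers": markers}
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_score_table(scores, outdir / "bw_scores.tsv")
        write_feature_panel(panel, outdir / "invariant_panel.tsv")
        for kk, C in result.consensus.items():
            pd.DataFrame(C, index=disc.sample_ids, columns=disc.sample_ids).to_csv(
                outdir / f"consensus_k{kk}.tsv", sep="\t", float_format="%.6g")
        pd.DataFrame({
            "k": list(result.cophenetic),
            "cophenetic": [result.cophenetic[kk] for kk in result.cophenetic],
        }).to_csv(outdir / "rank_selection.tsv", sep="\t", index=False)
        labels.rename_axis("sample_id").to_frame().to_csv(outdir / "subgroup_labels.tsv", sep="\t")
        write_model(model, outdir / "pam_model.tsv")
        markers.to_csv(outdir / "subgroup_markers.tsv", sep="\t")
        _write_manifest(outdir, config, "discovery", {
            "n_features_scored": len(scores), "n_panel": len(panel),
            "n_samples": disc.n_samples, "selected_k": k,
            "n_markers": len(markers),
        })
    return artifacts


def subgroup_survival_report(clinical: pd.DataFrame, labels: pd.Series,
                             config: PipelineConfig) -> dict:
    """Per-subgroup KM summaries, the omnibus log-rank test, and the
    treated-vs-untreated landmark comparison within each subgroup."""
    merged = clinical.set_index("sample_id").join(labels.rename("subgroup"), how="inner")
    merged = merged[merged["time_years"] > 0]
    t, e = surv.apply_horizon(merged["time_years"], merged["event"], config.horizon_years)

    km_rows = []
    for g, sub in merged.assign(t=t, e=e).groupby("subgroup"):
        curve = surv.km_estimate(sub["t"], sub["e"])
        km_rows.append({
            "subgroup": g, "n": len(sub), "events": int(sub["e"].sum()),
            "survival_at_horizon": curve.at(config.horizon_years),
        })
    km_table = pd.DataFrame(km_rows)

    omnibus = surv.logrank_test(t, e, merged["subgroup"].to_numpy())

    landmark = {}
    treated = merged["endocrine_treated"]
    for g, sub in merged.assign(t=t, e=e, tr=treated).groupby("subgroup"):
        known = sub[sub["tr"].isin([True, False])]
        if known["tr"].nunique() == 2 and known["e"].sum() > 0:
            landmark[g] = surv.landmark_compare(
                known["t"], known["e"], known["tr"].to_numpy(),
                landmark=config.landmark_years,
            )
    return {"km": km_table, "logrank": omnibus, "landmark": landmark}


def run_validation(model, cohorts, clinical: pd.DataFrame,
                   config: PipelineConfig, cohort_labels=None, outdir=None) -> dict:
    """Validation workflow: standardize, merge, classify, survival report."""
    cohorts = list(cohorts)
    if not cohorts:
        raise ValueError("need >= 1 validation cohort")
    standardized = [standardize_and_center(c) if c.scale != "standardized" else c
                    for c in cohorts]
    if len(standardized) == 1:
        merged = standardized[0]
    else:
        merged = merge_cohorts(standardized, labels=cohort_labels)
    result = classify(model, merged, threshold=config.confidence_threshold)
    calls = result.to_frame()
    log.info("classified %d samples; %.1f%% confident",
             len(calls), 100.0 * calls["confident"].mean())

    # survival uses the unprefixed sample IDs from the clinical table
    labels = pd.Series(result.predicted,
                       index=[s.split(":", 1)[-1] for s in result.sample_ids],
                       name="subgroup")
    report = subgroup_survival_report(clinical, labels, config)

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        calls.to_csv(outdir / "classification.tsv", sep="\t", float_format="%.6g")
        report["km"].to_csv(outdir / "subgroup_km.tsv", sep="\t", index=False)
        with open(outdir / "subgroup_logrank.tsv", "w") as fh:
            lr = report["logrank"]
            fh.write("statistic\tdf\tp_value\n")
            fh.write(f"{lr.statistic:.6g}\t{lr.df}\t{lr.p_value:.6g}\n")
        _write_manifest(outdir, config, "validation", {
            "n_samples": len(calls),
            "n_confident": int(calls["confident"].sum()),
        })
    return {"classification": result, "survival": report}
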