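"""Ground-truthed synthetic cohorts for the subgrouping pipeline.

Two generators mirror the two study designs the pipeline consumes:

``generate_paired_cohort``
    A paired pre/post endocrine-deprivation design (one tumor biopsied
    before and after treatment).  Genes come in three kinds:

    * *invariant* genes — a tumor-specific baseline shared by the pre and
      post sample (between-tumor variation, no treatment response),
    * *responsive* genes — a gene-specific pre-to-post shift applied to all
      tumors (treatment response, little between-tumor variation),
    * *noise* genes — residual noise only.

    These are exactly the signal classes the between/within (b/w) variance
    ratio is designed to separate.

``generate_subtyped_cohort``
    A single-timepoint cohort with ``k_true`` planted subgroups.  Each
    subgroup over-expresses its own block of signature genes, and survival
    times are exponential with a subgroup-specific scale, administratively
    censored.  This is the structure class discovery, classification, and
    subgroup survival comparison are expected to recover.

Expression is Gaussian on the log2 scale around a positive baseline
(post-RMA-like), so the unstandardized matrices are non-negative in
practice and feed non-negative factorization directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix

#: Typical log2 microarray intensity around which simulated genes fluctuate.
BASELINE_LOG2 = 7.0


@dataclass(frozen=True)
class PairedDesign:
    """Pairing of pre- and post-treatment samples of the same tumors."""

    tumor_ids: tuple
    pre_sample_ids: tuple
    post_sample_ids: tuple

    def __post_init__(self):
        n = len(self.tumor_ids)
        if len(self.pre_sample_ids) != n or len(self.post_sample_ids) != n:
            raise ValueError("tumor/pre/post ID lists must have equal length")
        all_ids = list(self.pre_sample_ids) + list(self.post_sample_ids)
        if len(set(all_ids)) != len(all_ids):
            raise ValueError("pre/post sample IDs must be distinct")

    @property
    def n_tumors(self) -> int:
        return len(self.tumor_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "tumor_id": self.tumor_ids,
            "pre_sample_id": self.pre_sample_ids,
            "post_sample_id": self.post_sample_ids,
        })

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "PairedDesign":
        return cls(tuple(df["tumor_id"]), tuple(df["pre_sample_id"]),
                   tuple(df["post_sample_id"]))


@dataclass(frozen=True)
class PairedCohortSpec:
    """Parameters of the paired pre/post cohort.

    Defaults match the desk-scale study conditions: 58 tumors (the size of
    the paired letrozole cohort), 10,000 genes of which 1,000 are
    treatment-invariant, between-tumor SD 2, treatment-shift SD 2, residual
    SD 0.5 (log2 units).
    """

    n_tumors: int = 58
    n_invariant_genes: int = 1000
    n_responsive_genes: int = 4000
    n_noise_genes: int = 5000
    between_sd: float = 2.0
    treatment_shift_sd: float = 2.0
    noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.n_tumors < 2:
            raise ValueError("n_tumors must be >= 2")
        for name in ("n_invariant_genes", "n_responsive_genes", "n_noise_genes"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("between_sd", "treatment_shift_sd", "noise_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


def generate_paired_cohort(spec: PairedCohortSpec):
    """Simulate a paired pre/post cohort.

    Returns
    -------
    (ExpressionMatrix, PairedDesign, pandas.Series)
        The expression matrix (2 * n_tumors samples), the pairing design,
        and per-gene truth labels in ``{'invariant', 'responsive', 'noise'}``.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_tumors
    width = len(str(n))
    tumors = tuple(f"T{i + 1:0{width}d}" for i in range(n))
    pre = tuple(f"{t}_pre" for t in tumors)
    post = tuple(f"{t}_post" for t in tumors)
    design = PairedDesign(tumors, pre, post)

    kinds = (["invariant"] * spec.n_invariant_genes
             + ["responsive"] * spec.n_responsive_genes
             + ["noise"] * spec.n_noise_genes)
    n_genes = len(kinds)
    gene_ids = [f"g{i + 1:05d}_{kinds[i][:3]}" for i in range(n_genes)]

    gene_level = BASELINE_LOG2 + rng.normal(0.0, 0.25, size=(n_genes, 1))
    pre_vals = np.tile(gene_level, (1, n))
    post_vals = pre_vals.copy()

    inv = slice(0, spec.n_invariant_genes)
    resp = slice(spec.n_invariant_genes, spec.n_invariant_genes + spec.n_responsive_genes)

    # invariant genes: tumor-specific baseline, identical pre and post
    baseline = rng.normal(0.0, spec.between_sd, size=(spec.n_invariant_genes, n))
    pre_vals[inv] += baseline
    post_vals[inv] += baseline

    # responsive genes: one pre->post shift per gene, applied to every tumor
    shift = rng.normal(0.0, spec.treatment_shift_sd, size=(spec.n_responsive_genes, 1))
    post_vals[resp] += shift

    pre_vals += rng.normal(0.0, spec.noise_sd, size=pre_vals.shape)
    post_vals += rng.normal(0.0, spec.noise_sd, size=post_vals.shape)

    data = pd.DataFrame(
        np.hstack([pre_vals, post_vals]),
        index=gene_ids, columns=list(pre) + list(post),
    )
    truth = pd.Series(kinds, index=gene_ids, name="gene_kind")
    return ExpressionMatrix(data, scale="log_intensity"), design, truth


@dataclass(frozen=True)
class SubtypedCohortSpec:
    """Parameters of the subgrouped single-timepoint cohort.

    Defaults match the desk-scale discovery conditions: 262 samples in 6
    subgroups, 50 signature genes per subgroup plus 200 unstructured genes,
    signature shift of 2 log2 units over residual SD 1.  Per-subgroup
    exponential survival scales are chosen so 10-year event-free fractions
    span roughly 50-90% (the spread observed across good- and poor-outcome
    subgroups), with administrative censoring at 10 years.
    """

    n_samples: int = 262
    k_true: int = 6
    n_signature_genes_per_group: int = 50
    n_noise_genes: int = 200
    signature_effect: float = 2.0
    noise_sd: float = 1.0
    survival_scales_years: tuple = (20.0, 60.0, 35.0, 14.0, 78.0, 55.0)
    censor_time_years: float = 10.0
    treated_fraction: float = 0.5
    endpoint: str = "DMFS"
    seed: int = 0

    def __post_init__(self):
        if self.k_true < 2:
            raise ValueError("k_true must be >= 2")
        if self.k_true > self.n_samples:
            raise ValueError("k_true exceeds n_samples")
        if len(self.survival_scales_years) != self.k_true:
            raise ValueError("survival_scales_years must have k_true entries")
        if any(s <= 0 for s in self.survival_scales_years):
            raise ValueError("survival scales must be > 0")
        if self.noise_sd <= 0 or self.censor_time_years <= 0:
            raise ValueError("noise_sd and censor_time_years must be > 0")
        if not (0.0 <= self.treated_fraction <= 1.0):
            raise ValueError("treated_fraction must be in [0, 1]")


def generate_subtyped_cohort(spec: SubtypedCohortSpec):
    """Simulate a cohort with planted subgroups and subgroup-dependent survival.

    Returns
    -------
    (ExpressionMatrix, pandas.Series, pandas.DataFrame)
        Expression matrix, true subgroup labels (ints 1..k_true indexed by
        sample ID), and a clinical table with columns ``sample_id``,
        ``time_years``, ``event``, ``endpoint``, ``endocrine_treated``,
        ``er_positive``.
    """
    rng = np.random.default_rng(spec.seed)
    n, k = spec.n_samples, spec.k_true
    width = len(str(n))
    samples = [f"S{i + 1:0{width}d}" for i in range(n)]

    # round-robin assignment (balanced groups), then a seeded shuffle
    groups = np.array([(i % k) + 1 for i in range(n)])
    rng.shuffle(groups)

    n_sig = spec.n_signature_genes_per_group
    gene_ids = [f"sig{g + 1}_{j + 1:03d}" for g in range(k) for j in range(n_sig)]
    gene_ids += [f"noise_{j + 1:04d}" for j in range(spec.n_noise_genes)]
    n_genes = len(gene_ids)

    values = BASELINE_LOG2 + rng.normal(0.0, spec.noise_sd, size=(n_genes, n))
    for g in range(k):
        rows = slice(g * n_sig, (g + 1) * n_sig)
        values[rows][:, groups == g + 1] += spec.signature_effect

    expr = ExpressionMatrix(
        pd.DataFrame(values, index=gene_ids, columns=samples), scale="log_intensity"
    )
    labels = pd.Series(groups, index=samples, name="subgroup")

    scales = np.asarray(spec.survival_scales_years, dtype=float)
    raw_times = rng.exponential(scale=scales[groups - 1])
    event = (raw_times <= spec.censor_time_years).astype(int)
    times = np.minimum(raw_times, spec.censor_time_years)
    treated = rng.random(n) < spec.treated_fraction

    clinical = pd.DataFrame({
        "sample_id": samples,
        "time_years": times,
        "event": event,
        "endpoint": spec.endpoint,
        "endocrine_treated": treated,
        "er_positive": True,
    })
    return expr, labels, clinical
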