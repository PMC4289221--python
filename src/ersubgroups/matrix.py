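"""Expression-matrix and clinical-table containers with loading, validation,
standardization, and cohort merging.

The central object is :class:`ExpressionMatrix`, a thin wrapper around a
features x samples :class:`pandas.DataFrame` that tracks the measurement
scale (``log_intensity`` for post-RMA microarray intensities,
``normalized_count`` for RSEM-style RNA-seq abundances, ``standardized``
after per-feature z-scoring).  Cohorts from different platforms are made
comparable by standardizing each feature within each cohort and merging on
the shared feature set, mirroring common practice for pooling independent
expression studies.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

SCALES = ("log_intensity", "normalized_count", "standardized")

#: Missing-value spellings recognized at load time.
_NA_STRINGS = {"", "NA", "N/A", "NaN", "nan", "null", "NULL"}


class MatrixLoadError(ValueError):
    """Raised for malformed expression-matrix files (names the offending cell/ID)."""


@dataclass
class ExpressionMatrix:
    """Features x samples real-valued expression matrix.

    Parameters
    ----------
    data : pandas.DataFrame
        Rows are features, columns are samples.  Index and columns must be
        unique; values must be finite.
    scale : str
        One of ``log_intensity``, ``normalized_count``, ``standardized``.
    constant_features : frozenset of str
        Features that had zero variance when the matrix was standardized.
        They are centered to 0 but carry no between-sample information and
        are excluded from variance-ratio ranking downstream.
    """

    data: pd.DataFrame
    scale: str = "log_intensity"
    constant_features: frozenset = field(default_factory=frozenset)
    #: True for merged multi-cohort matrices and sample subsets, where
    #: per-feature standardization holds only within the original blocks,
    #: so the global mean-0 / SD-1 validation is skipped.
    relaxed_standardization: bool = False

    def __post_init__(self) -> None:
        if self.scale not in SCALES:
            raise ValueError(f"unknown scale {self.scale!r}; expected one of {SCALES}")
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate feature IDs: {dups[:5]}")
        if self.data.columns.has_duplicates:
            dups = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample IDs: {dups[:5]}")
        values = self.data.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValueError("expression values must be numeric")
        if not np.all(np.isfinite(values)):
            i, j = np.argwhere(~np.isfinite(values))[0]
            raise ValueError(
                f"non-finite value at feature {self.data.index[i]!r}, "
                f"sample {self.data.columns[j]!r}"
            )
        if self.scale == "standardized":
            self._check_standardized()

    def _check_standardized(self, atol: float = 1e-8) -> None:
        if self.relaxed_standardization:
            return
        values = self.data.to_numpy()
        means = values.mean(axis=1)
        if not np.allclose(means, 0.0, atol=atol):
            raise ValueError("scale='standardized' but feature means are not 0")
        nonconst = ~self.data.index.isin(self.constant_features)
        if nonconst.any() and values.shape[1] > 1:
            sds = values[nonconst].std(axis=1, ddof=1)
            if not np.allclose(sds, 1.0, atol=atol):
                raise ValueError(
                    "scale='standardized' but non-constant feature SDs are not 1"
                )

    # -- convenience accessors -------------------------------------------------
    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def n_features(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def subset_features(self, features) -> "ExpressionMatrix":
        """Restrict to the given features (order preserved as given)."""
        missing = [f for f in features if f not in self.data.index]
        if missing:
            raise KeyError(f"features not in matrix: {missing[:5]}")
        return ExpressionMatrix(
            self.data.loc[list(features)],
            scale=self.scale,
            constant_features=frozenset(f for f in self.constant_features if f in set(features)),
            relaxed_standardization=self.relaxed_standardization,
        )

    def subset_samples(self, samples) -> "ExpressionMatrix":
        missing = [s for s in samples if s not in self.data.columns]
        if missing:
            raise KeyError(f"samples not in matrix: {missing[:5]}")
        return ExpressionMatrix(
            self.data[list(samples)], scale=self.scale,
            constant_features=self.constant_features, relaxed_standardization=True,
        )


def load_expression_matrix(
    path,
    orientation: str = "features_in_rows",
    scale: str = "log_intensity",
    impute_missing: bool = False,
) -> ExpressionMatrix:
    """Read a tab-delimited expression matrix.

    The file has one header row of sample IDs and a leading column of feature
    IDs (``orientation='features_in_rows'``), or the transpose
    (``orientation='samples_in_rows'``).

    Duplicate feature IDs are collapsed by keeping the duplicate row with the
    highest mean expression (a standard probe-collapse rule).  Duplicate
    sample IDs are an error.  Missing values are rejected unless
    ``impute_missing`` is set, in which case they are imputed with the
    per-feature median.
    """
    if orientation not in ("features_in_rows", "samples_in_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    text = Path(path).read_text()
    lines = text.splitlines()
    if not lines or not lines[0].strip():
        raise MatrixLoadError(f"{path}: empty or missing header row")
    header = lines[0].rstrip("\n").split("\t")
    col_ids = header[1:]
    if len(col_ids) == 0:
        raise MatrixLoadError(f"{path}: header row has no sample IDs")
    # pandas mangles duplicate header names, so duplicates must be caught here.
    # In the transposed orientation header IDs are features; collapsing them
    # would require unmangled parsing, so they are rejected in both cases.
    seen: set[str] = set()
    for cid in col_ids:
        if cid in seen:
            kind = "sample" if orientation == "features_in_rows" else "feature"
            raise MatrixLoadError(f"{path}: duplicate {kind} ID {cid!r} in header")
        seen.add(cid)

    raw = pd.read_csv(io.StringIO(text), sep="\t", index_col=0, dtype=str)
    numeric = raw.apply(lambda col: pd.to_numeric(col, errors="coerce"))
    bad = numeric.isna() & ~raw.isin(_NA_STRINGS) & raw.notna()
    if bad.to_numpy().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        raise MatrixLoadError(
            f"{path}: non-numeric value {raw.iat[i, j]!r} at row {raw.index[i]!r}, "
            f"column {raw.columns[j]!r} (data cell ({i + 1},{j + 1}))"
        )

    if orientation == "samples_in_rows":
        numeric = numeric.T

    if numeric.columns.has_duplicates:
        dup = numeric.columns[numeric.columns.duplicated()].unique().tolist()
        raise MatrixLoadError(f"{path}: duplicate sample ID {dup[0]!r}")

    # collapse duplicated feature IDs: keep the row with the highest mean
    if numeric.index.has_duplicates:
        means = numeric.mean(axis=1, skipna=True).to_numpy()
        keep_pos: dict[str, int] = {}
        for pos, fid in enumerate(numeric.index):
            if fid not in keep_pos or means[pos] > means[keep_pos[fid]]:
                keep_pos[fid] = pos
        numeric = numeric.iloc[sorted(keep_pos.values())]

    if numeric.isna().to_numpy().any():
        if not impute_missing:
            i, j = np.argwhere(numeric.isna().to_numpy())[0]
            raise MatrixLoadError(
                f"{path}: missing value at feature {numeric.index[i]!r}, "
                f"sample {numeric.columns[j]!r} (pass impute_missing=True to impute)"
            )
        med = numeric.median(axis=1)
        numeric = numeric.apply(lambda col: col.fillna(med))

    return ExpressionMatrix(numeric.astype(float), scale=scale)


def write_expression_matrix(m: ExpressionMatrix, path) -> None:
    """Write tab-delimited (features in rows); round-trips values to 1e-12."""
    m.data.to_csv(path, sep="\t", float_format="%.17g")


def standardize_and_center(m: ExpressionMatrix) -> ExpressionMatrix:
    """Per-feature z-scoring: subtract the feature mean, divide by the feature
    sample SD (n-1 denominator).

    Constant features are centered to 0 and flagged in
    ``constant_features``; they cannot be rescaled (SD 0) and carry no
    ranking information downstream.
    """
    if m.scale == "standardized":
        return m
    if m.n_samples < 2:
        raise ValueError("standardization needs >= 2 samples (sample SD undefined)")
    values = m.values.astype(float)
    means = values.mean(axis=1, keepdims=True)
    sds = values.std(axis=1, ddof=1, keepdims=True)
    const = (sds[:, 0] == 0.0)
    sds[const] = 1.0
    out = (values - means) / sds
    out[const] = 0.0
    return ExpressionMatrix(
        pd.DataFrame(out, index=m.data.index, columns=m.data.columns),
        scale="standardized",
        constant_features=frozenset(np.asarray(m.feature_ids)[const].tolist()),
    )


def merge_cohorts(cohorts, labels=None) -> ExpressionMatrix:
    """Column-concatenate standardized cohorts on their shared features.

    Features are restricted to the intersection of feature IDs (ordered as in
    the first cohort); sample IDs are prefixed ``<label>:`` to guarantee
    uniqueness across cohorts.
    """
    cohorts = list(cohorts)
    if len(cohorts) < 2:
        raise ValueError("merge_cohorts needs >= 2 cohorts")
    for i, c in enumerate(cohorts):
        if c.scale != "standardized":
            raise ValueError(f"cohort {i} is not standardized (scale={c.scale!r})")
    if labels is None:
        labels = [f"cohort{i + 1}" for i in range(len(cohorts))]
    if len(labels) != len(cohorts) or len(set(labels)) != len(labels):
        raise ValueError("labels must be unique, one per cohort")

    shared = set(cohorts[0].feature_ids)
    for c in cohorts[1:]:
        shared &= set(c.feature_ids)
    if not shared:
        raise ValueError("empty feature intersection across cohorts")
    order = [f for f in cohorts[0].feature_ids if f in shared]

    blocks = []
    const: set[str] = set()
    for lab, c in zip(labels, cohorts):
        block = c.data.loc[order].copy()
        block.columns = [f"{lab}:{s}" for s in block.columns]
        blocks.append(block)
        const |= {f for f in c.constant_features if f in shared}
    merged = pd.concat(blocks, axis=1)
    return ExpressionMatrix(merged, scale="standardized",
                            constant_features=frozenset(const), relaxed_standardization=True)


DEFAULT_ESR1_CUTOFF = 250.0  # RSEM normalized counts


def call_er_status(expr: float, cutoff: float = DEFAULT_ESR1_CUTOFF) -> str:
    """ER status call from ESR1 normalized-count expression.

    ``positive`` iff ``expr >= cutoff`` (the boundary value counts as
    positive).  The default cutoff of 250 RSEM normalized counts is the
    conventional threshold for calling ER positivity from RNA-seq.
    """
    if expr < 0:
        raise ValueError(f"negative expression value {expr}")
    if cutoff < 0:
        raise ValueError(f"negative cutoff {cutoff}")
    return "positive" if expr >= cutoff else "negative"


# -- clinical tables ----------------------------------------------------------

CLINICAL_COLUMNS = [
    "sample_id", "time_years", "event", "endpoint", "endocrine_treated", "er_positive",
]
ENDPOINTS = ("DFS", "DMFS")
_TRISTATE = {"true": True, "false": False, "unknown": None,
             "1": True, "0": False, "": None, "na": None}


def validate_clinical_table(table: pd.DataFrame) -> pd.DataFrame:
    """Validate a clinical table (one row per sample, non-negative times,
    0/1 events, DFS/DMFS endpoint, tri-state treatment and ER flags)."""
    missing = [c for c in CLINICAL_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"clinical table missing columns: {missing}")
    t = table[CLINICAL_COLUMNS].copy()
    if t["sample_id"].duplicated().any():
        dup = t.loc[t["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValueError(f"duplicate sample_id {dup!r} in clinical table")
    t["time_years"] = pd.to_numeric(t["time_years"])
    if (t["time_years"] < 0).any():
        raise ValueError("negative time_years in clinical table")
    t["event"] = pd.to_numeric(t["event"]).astype(int)
    if not t["event"].isin([0, 1]).all():
        raise ValueError("event must be 0 or 1")
    if not t["endpoint"].isin(ENDPOINTS).all():
        bad = t.loc[~t["endpoint"].isin(ENDPOINTS), "endpoint"].iloc[0]
        raise ValueError(f"unknown endpoint {bad!r}; expected one of {ENDPOINTS}")
    for col in ("endocrine_treated", "er_positive"):
        t[col] = [
            _TRISTATE[str(v).strip().lower()] if not isinstance(v, bool) and v is not None
            else v
            for v in t[col]
        ]
    return t


def load_clinical_table(path) -> pd.DataFrame:
    return validate_clinical_table(pd.read_csv(path, sep="\t", dtype={"sample_id": str}))


def write_clinical_table(table: pd.DataFrame, path) -> None:
    out = table.copy()
    for col in ("endocrine_treated", "er_positive"):
        out[col] = [
            "unknown" if v is None else ("true" if v else "false") for v in out[col]
        ]
    out.to_csv(path, sep="\t", index=False)
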