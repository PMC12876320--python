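"""Expression containers, TSV I/O, and the small normalization utilities.

The bulk RNA-seq side of the package works on a gene x sample integer count
matrix plus a per-sample metadata table (donor, hemisphere, Brodmann area and
donor-level covariates).  Normalizations implemented here: TMM library-scaling
factors, log2-CPM, TPM, per-gene Z-scores, coefficient-of-variation ranking,
and the 2^-ddCt relative-quantification fold change for qPCR.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

HEMISPHERES = ("L", "R")

META_COLUMNS = [
    "sample_id",
    "donor",
    "hemisphere",
    "area",
    "sex",
    "age",
    "handedness",
    "family_history",
    "language_disorder",
]

NORMALIZATION_UNITS = ("logCPM", "TPM", "zscore")


class ExpressionDataError(ValueError):
    """Raised for malformed count matrices or metadata."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class CountMatrix:
    """Non-negative integer gene x sample count matrix."""

    gene_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ExpressionDataError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ExpressionDataError("duplicate gene IDs")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ExpressionDataError("duplicate sample IDs")
        if np.any(self.counts < 0):
            raise ExpressionDataError("negative counts")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.allclose(self.counts, np.round(self.counts)):
                raise ExpressionDataError("counts must be integers")
            self.counts = self.counts.astype(np.int64)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.gene_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CountMatrix":
        return cls(list(df.index), list(df.columns), df.to_numpy())

    def subset_samples(self, sample_ids: list[str]) -> "CountMatrix":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return CountMatrix(list(self.gene_ids), list(sample_ids), self.counts[:, idx])


@dataclass
class NormalizedMatrix:
    """Real-valued gene x sample matrix with a unit tag.

    ``size_factors`` carries the per-sample effective library sizes (logCPM)
    or is all-ones for unit-free transforms.  ``meta`` holds transform
    parameters needed to invert (e.g. per-gene mean/sd for Z-scores).
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    unit: str
    size_factors: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.unit not in NORMALIZATION_UNITS:
            raise ExpressionDataError(f"unknown unit tag {self.unit!r}")
        if self.size_factors is not None:
            self.size_factors = np.asarray(self.size_factors, dtype=float)
            if np.any(self.size_factors <= 0):
                raise ExpressionDataError("size factors must be positive")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)


def validate_meta(meta: pd.DataFrame, counts: CountMatrix | None = None) -> pd.DataFrame:
    """Check a sample-metadata table; optionally against a count matrix."""
    missing_cols = [c for c in META_COLUMNS if c not in meta.columns]
    if missing_cols:
        raise ExpressionDataError(f"metadata missing columns: {missing_cols}")
    if meta["sample_id"].duplicated().any():
        dups = meta.loc[meta["sample_id"].duplicated(), "sample_id"].tolist()
        raise ExpressionDataError(f"duplicate sample_id in metadata: {dups}")
    bad_hemi = set(meta["hemisphere"]) - set(HEMISPHERES)
    if bad_hemi:
        raise ExpressionDataError(f"hemisphere must be L or R, got {sorted(bad_hemi)}")
    if meta["area"].isna().any():
        raise ExpressionDataError("area must be non-missing for every sample")
    if counts is not None:
        meta_ids = set(meta["sample_id"])
        count_ids = set(counts.sample_ids)
        only_counts = sorted(count_ids - meta_ids)
        only_meta = sorted(meta_ids - count_ids)
        if only_counts or only_meta:
            raise ExpressionDataError(
                "sample sets differ between counts and metadata: "
                f"missing from metadata {only_counts}, missing from counts {only_meta}"
            )
    return meta


# ---------------------------------------------------------------------------
# TSV I/O
# ---------------------------------------------------------------------------


def read_counts(counts_path, meta_path) -> tuple[CountMatrix, pd.DataFrame]:
    """Read a counts TSV (genes as rows) and its sample-metadata TSV."""
    df = pd.read_csv(counts_path, sep="\t", index_col=0)
    if (df.to_numpy() < 0).any():
        raise ExpressionDataError(f"negative count in {counts_path}")
    cm = CountMatrix.from_frame(df)
    meta = pd.read_csv(meta_path, sep="\t", dtype={"sample_id": str, "donor": str})
    validate_meta(meta, cm)
    return cm, meta


def write_counts(cm: CountMatrix, meta: pd.DataFrame, counts_path, meta_path) -> None:
    cm.to_frame().to_csv(counts_path, sep="\t", index_label="gene_id")
    meta.to_csv(meta_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# TMM library scaling
# ---------------------------------------------------------------------------


def tmm_factors(
    cm: CountMatrix,
    trim_logratio: float = 0.30,
    trim_abs: float = 0.05,
    ref: int | None = None,
) -> np.ndarray:
    """Trimmed mean of M-values scaling factors.

    M-values (log2 relative expression vs the reference library) are doubly
    trimmed: ``trim_logratio`` from each tail of M and ``trim_abs`` from each
    tail of A (log2 mean abundance); the factor is 2**(precision-weighted mean
    of the surviving M-values).  Factors are rescaled so their geometric mean
    is 1.  The reference library defaults to the one whose depth is closest
    to the median depth.
    """
    counts = cm.counts.astype(float)
    if counts.shape[1] < 2:
        raise ExpressionDataError("TMM needs at least 2 samples")
    lib = counts.sum(axis=0)
    if np.any(lib == 0):
        bad = [cm.sample_ids[i] for i in np.where(lib == 0)[0]]
        raise ExpressionDataError(f"all-zero sample(s): {bad}")
    if ref is None:
        ref = int(np.argmin(np.abs(lib - np.median(lib))))

    factors = np.ones(counts.shape[1])
    yr, nr = counts[:, ref], lib[ref]
    for k in range(counts.shape[1]):
        if k == ref:
            continue
        yk, nk = counts[:, k], lib[k]
        ok = (yk > 0) & (yr > 0)
        if not ok.any():
            continue
        m = np.log2((yk[ok] / nk) / (yr[ok] / nr))
        a = 0.5 * np.log2((yk[ok] / nk) * (yr[ok] / nr))
        w = (nk - yk[ok]) / (nk * yk[ok]) + (nr - yr[ok]) / (nr * yr[ok])
        finite = np.isfinite(m) & np.isfinite(a) & np.isfinite(w)
        m, a, w = m[finite], a[finite], w[finite]
        n = m.size
        if n == 0:
            continue
        if np.max(np.abs(m)) < 1e-10:
            continue  # pure depth scaling
        lo_m = int(np.floor(n * trim_logratio)) + 1
        hi_m = n + 1 - lo_m
        lo_a = int(np.floor(n * trim_abs)) + 1
        hi_a = n + 1 - lo_a
        rank_m = pd.Series(m).rank().to_numpy()
        rank_a = pd.Series(a).rank().to_numpy()
        keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
        if keep.sum() == 0 or w[keep].sum() == 0:
            continue
        factors[k] = 2.0 ** (np.sum(w[keep] * m[keep]) / np.sum(w[keep]))

    factors = factors / np.exp(np.mean(np.log(factors)))
    return factors


# ---------------------------------------------------------------------------
# normalizations
# ---------------------------------------------------------------------------


def log_cpm(
    cm: CountMatrix,
    size_factors: np.ndarray | None = None,
    prior_count: float = 0.5,
) -> NormalizedMatrix:
    """log2 counts per million on TMM-effective library sizes.

    value = log2((count + prior_count) / effective_library_size * 1e6).
    """
    counts = cm.counts.astype(float)
    lib = counts.sum(axis=0)
    if size_factors is None:
        size_factors = np.ones(cm.n_samples)
    size_factors = np.asarray(size_factors, dtype=float)
    if np.any(size_factors <= 0):
        raise ExpressionDataError("size factors must be positive")
    eff = lib * size_factors
    if prior_count <= 0 and np.any(counts == 0):
        raise ExpressionDataError(
            "prior_count must be > 0 when zero counts are present (log of 0)"
        )
    vals = np.log2((counts + prior_count) / eff[None, :] * 1e6)
    return NormalizedMatrix(
        list(cm.gene_ids), list(cm.sample_ids), vals, "logCPM", size_factors=eff
    )


def tpm_from_counts(cm: CountMatrix, gene_lengths) -> NormalizedMatrix:
    """Transcripts per million from counts and gene lengths (bp).

    Each sample column sums to 1e6.
    """
    if isinstance(gene_lengths, dict):
        gene_lengths = pd.Series(gene_lengths)
    missing = [g for g in cm.gene_ids if g not in gene_lengths.index]
    if missing:
        raise ExpressionDataError(f"missing gene length for: {missing[:5]}")
    lengths = gene_lengths.loc[cm.gene_ids].to_numpy(dtype=float)
    if np.any(lengths <= 0):
        raise ExpressionDataError("gene lengths must be positive")
    rate = cm.counts / lengths[:, None]
    denom = rate.sum(axis=0)
    if np.any(denom == 0):
        bad = [cm.sample_ids[i] for i in np.where(denom == 0)[0]]
        raise ExpressionDataError(f"all-zero sample(s), TPM undefined: {bad}")
    vals = rate / denom[None, :] * 1e6
    return NormalizedMatrix(list(cm.gene_ids), list(cm.sample_ids), vals, "TPM")


def cv_rank(nm: NormalizedMatrix, top_fraction: float = 0.2) -> pd.DataFrame:
    """Per-gene coefficient of variation (sd/mean, sample sd) and a flag for
    the top fraction of most variable genes; ties broken by gene ID order."""
    if nm.values.shape[1] < 2:
        raise ExpressionDataError("CV needs at least 2 samples")
    mean = nm.values.mean(axis=1)
    sd = nm.values.std(axis=1, ddof=1)
    cv = np.full(mean.shape, np.nan)
    valid = mean != 0
    if (~valid).any():
        warnings.warn(f"{int((~valid).sum())} zero-mean gene(s) excluded from CV ranking")
    cv[valid] = sd[valid] / mean[valid]
    out = pd.DataFrame({"gene_id": nm.gene_ids, "cv": cv})
    n_valid = int(valid.sum())
    n_top = int(top_fraction * n_valid)
    order = out.loc[valid].sort_values(
        ["cv", "gene_id"], ascending=[False, True], kind="mergesort"
    )
    top_genes = set(order["gene_id"].head(n_top))
    out["top"] = out["gene_id"].isin(top_genes)
    return out


def zscore(nm: NormalizedMatrix) -> NormalizedMatrix:
    """Per-gene Z-scores (mean 0, sample sd 1); constant genes map to zeros."""
    mean = nm.values.mean(axis=1)
    sd = nm.values.std(axis=1, ddof=1)
    flat = sd == 0
    if flat.any():
        warnings.warn(f"{int(flat.sum())} constant gene(s) set to zero Z-scores")
    safe_sd = np.where(flat, 1.0, sd)
    vals = (nm.values - mean[:, None]) / safe_sd[:, None]
    vals[flat, :] = 0.0
    return NormalizedMatrix(
        list(nm.gene_ids),
        list(nm.sample_ids),
        vals,
        "zscore",
        meta={"mean": mean, "sd": sd},
    )


# ---------------------------------------------------------------------------
# qPCR relative quantification
# ---------------------------------------------------------------------------


@dataclass
class DdctRecord:
    """Cycle thresholds for target/reference genes in test/control conditions."""

    ct_target_test: float
    ct_ref_test: float
    ct_target_ctrl: float
    ct_ref_ctrl: float

    def __post_init__(self) -> None:
        vals = [self.ct_target_test, self.ct_ref_test, self.ct_target_ctrl, self.ct_ref_ctrl]
        if not all(np.isfinite(v) and v > 0 for v in vals):
            raise ExpressionDataError("all Ct values must be finite and > 0")


def ddct_fold_change(rec: DdctRecord) -> float:
    """Relative expression fold change by the 2^-ddCt method."""
    dct_test = rec.ct_target_test - rec.ct_ref_test
    dct_ctrl = rec.ct_target_ctrl - rec.ct_ref_ctrl
    return float(2.0 ** (-(dct_test - dct_ctrl)))
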