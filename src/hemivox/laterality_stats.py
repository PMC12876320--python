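"""Lateralization summaries of the donor-paired contrasts.

Significant-gene counts per contrast, log10(n+1) count maps, the dumbbell
statistic (per within-hemisphere area pair: n_left, n_right, delta = absolute
count difference, and the Jaccard distance between the left and right
significant-gene sets), overlap with external disease gene sets, and per-gene
left-right Wilcoxon tests on normalized expression.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .expression_io import NormalizedMatrix


def count_significant(
    results: dict | pd.DataFrame, q_field: str = "q_contrast", alpha: float = 0.05
):
    """Number of genes with q_field < alpha, per contrast (or for one table)."""
    if isinstance(results, pd.DataFrame):
        if q_field not in results.columns:
            raise KeyError(f"unknown q_field {q_field!r}")
        return int((results[q_field] < alpha).sum())
    return {k: count_significant(df, q_field, alpha) for k, df in results.items()}


def significant_set(df: pd.DataFrame, q_field: str = "q_contrast", alpha: float = 0.05) -> set:
    if q_field not in df.columns:
        raise KeyError(f"unknown q_field {q_field!r}")
    return set(df.loc[df[q_field] < alpha, "gene_id"])


def log_count_map(counts) -> np.ndarray:
    """Elementwise log10(n + 1) of a count array/matrix."""
    arr = np.asarray(counts, dtype=float)
    if np.any(arr < 0):
        raise ValueError("counts must be non-negative")
    return np.log10(arr + 1.0)


def jaccard_distance(set_a, set_b) -> float:
    """J = 1 - |A intersect B| / |A union B|; both-empty defined as 0."""
    a, b = set(set_a), set(set_b)
    union = a | b
    if not union:
        warnings.warn("Jaccard distance of two empty sets defined as 0")
        return 0.0
    return 1.0 - len(a & b) / len(union)


def dumbbell_table(
    left_results: dict,
    right_results: dict,
    alpha: float = 0.05,
    q_field: str = "q_contrast",
) -> pd.DataFrame:
    """Per area-pair lateralization summary, ranked.

    ``left_results`` / ``right_results`` map (area_a, area_b) -> contrast
    table (or full (family, a, b) keys; family is stripped).  Pairs present in
    only one hemisphere are excluded with a warning.  Ranking: delta
    descending, ties by Jaccard distance descending, then by pair label.
    """

    def _norm(d: dict) -> dict:
        return {((k[1], k[2]) if len(k) == 3 else tuple(k)): v for k, v in d.items()}

    left, right = _norm(left_results), _norm(right_results)
    only = set(left) ^ set(right)
    if only:
        warnings.warn(f"area pairs present in one hemisphere only, excluded: {sorted(only)}")
    rows = []
    for pair in sorted(set(left) & set(right)):
        sl = significant_set(left[pair], q_field, alpha)
        sr = significant_set(right[pair], q_field, alpha)
        rows.append(
            {
                "area_a": pair[0],
                "area_b": pair[1],
                "n_left": len(sl),
                "n_right": len(sr),
                "delta": abs(len(sl) - len(sr)),
                "jaccard": jaccard_distance(sl, sr),
            }
        )
    df = pd.DataFrame(
        rows, columns=["area_a", "area_b", "n_left", "n_right", "delta", "jaccard"]
    )
    if len(df):
        df = df.sort_values(
            ["delta", "jaccard", "area_a", "area_b"],
            ascending=[False, False, True, True],
            kind="mergesort",
        ).reset_index(drop=True)
        df["rank"] = np.arange(1, len(df) + 1)
    else:
        df["rank"] = pd.Series(dtype=int)
    return df


def external_overlap(cohort_deg_set, disease_deg_sets) -> tuple[int, int, float]:
    """Fraction of cohort DEGs found in at least one external disease set.

    Returns (n_overlap, n_total, percent rounded to 1 decimal).
    """
    cohort = set(cohort_deg_set)
    if not cohort:
        raise ValueError("cohort DEG set is empty")
    union = set()
    for s in disease_deg_sets:
        union |= set(s)
    n_overlap = len(cohort & union)
    n_total = len(cohort)
    return n_overlap, n_total, round(100.0 * n_overlap / n_total, 1)


def wilcoxon_lr(
    values: NormalizedMatrix,
    meta: pd.DataFrame,
    gene: str,
    area: str,
    paired: bool = True,
) -> dict:
    """Left-right Wilcoxon test for one gene in one area.

    Paired (default, matching the donor-paired design): signed-rank test on
    per-donor right-minus-left differences, zero differences dropped.
    Unpaired: rank-sum.  Exact null for small n, normal approximation with
    continuity correction otherwise.  Returns dict(statistic, p, n, flag).
    """
    if gene not in values.gene_ids:
        raise KeyError(f"gene {gene!r} not in matrix")
    gi = values.gene_ids.index(gene)
    sel = meta["area"] == area
    sub = meta.loc[sel]
    col_idx = {s: i for i, s in enumerate(values.sample_ids)}

    def _vals(rows) -> np.ndarray:
        return np.array([values.values[gi, col_idx[s]] for s in rows["sample_id"]])

    left = sub[sub["hemisphere"] == "L"].set_index("donor")
    right = sub[sub["hemisphere"] == "R"].set_index("donor")
    if paired:
        donors = [d for d in left.index if d in right.index]
        if len(donors) < 2:
            raise ValueError("need >= 2 donor pairs")
        d = np.array(
            [
                values.values[gi, col_idx[right.loc[dn, "sample_id"]]]
                - values.values[gi, col_idx[left.loc[dn, "sample_id"]]]
                for dn in donors
            ]
        )
        nz = d[d != 0]
        if nz.size == 0:
            return {"statistic": np.nan, "p": 1.0, "n": 0, "flag": "all-zero-differences"}
        method = "exact" if nz.size <= 25 else "approx"
        res = stats.wilcoxon(nz, zero_method="wilcox", method=method, correction=True)
        return {"statistic": float(res.statistic), "p": float(res.pvalue), "n": int(nz.size),
                "flag": None}
    xl, xr = _vals(left.reset_index()), _vals(right.reset_index())
    if len(xl) < 2 or len(xr) < 2:
        raise ValueError("need >= 2 samples per group")
    if np.all(np.concatenate([xl, xr]) == xl[0]):
        return {"statistic": np.nan, "p": 1.0, "n": len(xl) + len(xr), "flag": "all-tied"}
    method = "exact" if len(xl) + len(xr) <= 25 else "asymptotic"
    res = stats.mannwhitneyu(xr, xl, alternative="two-sided", method=method)
    return {"statistic": float(res.statistic), "p": float(res.pvalue),
            "n": len(xl) + len(xr), "flag": None}
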