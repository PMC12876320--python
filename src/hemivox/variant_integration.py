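"""GWAS -> LD -> eQTL -> enhancer variant-integration cascade.

Sentinel selection (association p < 1e-5), LD expansion (proxies with
r-squared > 0.8 within a symmetric window), haplotype r-squared computation,
cis-eQTL intersection and eGene collapsing, genomic-region annotation with an
exonic > UTR > intronic > upstream/downstream > intergenic precedence,
super-enhancer / typical-enhancer colocalization with McNemar's exact test,
JASPAR position-weight-matrix allele scoring in log2-odds bits, Spearman
expression correlation, and intersection of eGenes with nominal DEG events.

Coordinate conventions: variant positions are 1-based (VCF/GWAS style);
enhancer and gene-model intervals are 0-based half-open internally (GFF3's
1-based closed intervals are converted on read).
"""

from __future__ import annotations

import itertools
import math
import warnings

import numpy as np
import pandas as pd
from scipy import stats


class VariantError(ValueError):
    pass


# ---------------------------------------------------------------------------
# sentinels and LD
# ---------------------------------------------------------------------------


def select_sentinels(gwas: pd.DataFrame, p_max: float = 1e-5) -> pd.DataFrame:
    """Sentinel variants with association p < p_max, deduplicated by rsid
    keeping the smallest p."""
    p = pd.to_numeric(gwas["p"], errors="coerce")
    bad = p.isna() | (p <= 0) | (p > 1)
    if bad.any():
        raise VariantError(
            f"malformed p value(s) for rsid(s): {gwas.loc[bad, 'rsid'].tolist()[:5]}"
        )
    out = gwas.assign(p=p).loc[p < p_max]
    out = out.sort_values("p", kind="mergesort").drop_duplicates("rsid", keep="first")
    out = out.sort_index().reset_index(drop=True)
    out["source"] = "index"
    return out


def compute_r2(n_AB, n_Ab, n_aB, n_ab) -> float:
    """Pairwise LD r-squared from the four haplotype counts.

    r2 = D^2 / (pA * pa * pB * pb) with D = pAB - pA*pB.  Returns NaN when a
    marginal allele frequency is zero (monomorphic locus, r2 undefined).
    """
    counts = np.array([n_AB, n_Ab, n_aB, n_ab], dtype=float)
    if np.any(counts < 0):
        raise VariantError("haplotype counts must be non-negative")
    total = counts.sum()
    if total == 0:
        raise VariantError("total haplotype count must be positive")
    p_ab, p_aB, p_Ab, p_AB = counts[3] / total, counts[2] / total, counts[1] / total, counts[0] / total
    p_a1 = p_AB + p_Ab  # freq of A at locus 1
    p_b1 = p_AB + p_aB  # freq of B at locus 2
    denom = p_a1 * (1 - p_a1) * p_b1 * (1 - p_b1)
    if denom == 0:
        return float("nan")
    d = p_AB - p_a1 * p_b1
    return float(d * d / denom)


def compute_r2_from_panel(hap_a: np.ndarray, hap_b: np.ndarray) -> float:
    """r-squared between two 0/1 haplotype vectors of one panel."""
    a = np.asarray(hap_a).astype(bool)
    b = np.asarray(hap_b).astype(bool)
    if a.shape != b.shape:
        raise VariantError("haplotype vectors must have equal length")
    return compute_r2(
        int(np.sum(a & b)), int(np.sum(a & ~b)), int(np.sum(~a & b)), int(np.sum(~a & ~b))
    )


def ld_expand(
    sentinels: pd.DataFrame,
    ld: pd.DataFrame,
    positions: pd.DataFrame,
    r2_min: float = 0.8,
    window_bp: int = 500_000,
) -> pd.DataFrame:
    """Expand sentinels to high-LD proxies.

    Keeps variants with r2 strictly greater than ``r2_min`` that lie within
    ``window_bp`` of their sentinel on the same chromosome.  ``positions``
    maps rsid -> (chrom, pos).  Sentinels absent from the LD source are
    skipped with a warning.  The proxy set is deduplicated by rsid (keeping
    the highest r2) and excludes the sentinels themselves.
    """
    pos = positions.set_index("rsid")
    sent_ids = set(sentinels["rsid"])
    partners = {}
    for _, row in ld.iterrows():
        a, b, r2 = row["rsid_a"], row["rsid_b"], row["r2"]
        for s, o in ((a, b), (b, a)):
            if s in sent_ids:
                partners.setdefault(s, []).append((o, r2))
    rows = []
    for s in sentinels["rsid"]:
        if s not in partners:
            warnings.warn(f"sentinel {s} absent from LD source, skipped")
            continue
        if s not in pos.index:
            warnings.warn(f"sentinel {s} has no position, skipped")
            continue
        s_chrom, s_pos = pos.loc[s, "chrom"], pos.loc[s, "pos"]
        for other, r2 in partners[s]:
            if other in sent_ids or not np.isfinite(r2) or r2 <= r2_min:
                continue
            if other not in pos.index:
                continue
            o_chrom, o_pos = pos.loc[other, "chrom"], pos.loc[other, "pos"]
            if o_chrom != s_chrom or abs(int(o_pos) - int(s_pos)) > window_bp:
                continue
            rows.append(
                {"rsid": other, "chrom": o_chrom, "pos": int(o_pos), "r2": float(r2),
                 "parent_rsid": s, "source": "proxy"}
            )
    out = pd.DataFrame(rows, columns=["rsid", "chrom", "pos", "r2", "parent_rsid", "source"])
    if len(out):
        out = (
            out.sort_values("r2", ascending=False, kind="mergesort")
            .drop_duplicates("rsid", keep="first")
            .sort_values(["chrom", "pos"], kind="mergesort")
            .reset_index(drop=True)
        )
    return out


# ---------------------------------------------------------------------------
# eQTL intersection
# ---------------------------------------------------------------------------


def intersect_eqtl(
    variants: pd.DataFrame, eqtl: pd.DataFrame, join_on: str = "rsid"
) -> tuple[pd.DataFrame, list[str], pd.Series]:
    """Inner-join variants with cis-eQTL records.

    Returns (hits, sorted eGene list, per-tissue hit counts).  ``join_on`` is
    "rsid" or "pos" (chrom+pos fallback with allele-consistency check;
    mismatching records are excluded with a warning).
    """
    if join_on == "rsid":
        hits = variants.merge(eqtl, on="rsid", how="inner", suffixes=("", "_eqtl"))
    elif join_on == "pos":
        hits = variants.merge(eqtl, on=["chrom", "pos"], how="inner", suffixes=("", "_eqtl"))
        if {"ref", "alt", "ref_eqtl", "alt_eqtl"} <= set(hits.columns):
            ok = (hits["ref"] == hits["ref_eqtl"]) & (hits["alt"] == hits["alt_eqtl"])
            if (~ok).any():
                warnings.warn(f"{int((~ok).sum())} record(s) excluded: allele mismatch")
            hits = hits.loc[ok]
    else:
        raise VariantError(f"unknown join key {join_on!r}")
    hits = hits.drop_duplicates(["rsid", "gene_id", "tissue"]).reset_index(drop=True)
    egenes = sorted(hits["gene_id"].unique())
    tissue_counts = hits["tissue"].value_counts()
    return hits, egenes, tissue_counts


# ---------------------------------------------------------------------------
# genomic-region annotation
# ---------------------------------------------------------------------------

REGION_PRECEDENCE = ["exonic", "UTR", "intronic", "upstream", "downstream", "intergenic"]


def read_gff3_model(path) -> pd.DataFrame:
    """Flatten a GFF3 gene model into (chrom, start, end, strand, type, gene_id)
    with 0-based half-open coordinates; feature types are mapped to
    gene / exon / UTR."""
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    rows = []
    for f in db.all_features():
        ftype = f.featuretype.lower()
        if ftype == "gene":
            kind = "gene"
        elif ftype == "exon":
            kind = "exon"
        elif "utr" in ftype:
            kind = "UTR"
        else:
            continue
        attrs = dict(f.attributes)
        if kind == "gene":
            gene_id = (attrs.get("gene_id") or attrs.get("ID") or ["?"])[0]
        else:
            gene_id = (attrs.get("gene_id") or attrs.get("Parent") or attrs.get("ID") or ["?"])[0]
        rows.append(
            {"chrom": f.seqid, "start": f.start - 1, "end": f.end, "strand": f.strand,
             "type": kind, "gene_id": gene_id}
        )
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "strand", "type", "gene_id"])


def annotate_region(
    variants: pd.DataFrame, model: pd.DataFrame, flank_bp: int = 2000
) -> pd.Series:
    """Classify each variant (1-based pos) against a 0-based half-open gene
    model: exonic > UTR > intronic > upstream/downstream (within ``flank_bp``
    of the TSS/TES, strand respected) > intergenic."""
    required = {"chrom", "start", "end", "strand", "type", "gene_id"}
    if not required <= set(model.columns):
        raise VariantError(f"gene model missing columns {required - set(model.columns)}")
    if (model["start"] >= model["end"]).any():
        raise VariantError("malformed feature: start must be < end (half-open)")
    rank = {c: i for i, c in enumerate(REGION_PRECEDENCE)}
    genes = model.loc[model["type"] == "gene"]
    labels = []
    for _, v in variants.iterrows():
        pos0 = int(v["pos"]) - 1
        best = "intergenic"

        def consider(cls: str) -> None:
            nonlocal best
            if rank[cls] < rank[best]:
                best = cls

        feat = model.loc[
            (model["chrom"] == v["chrom"]) & (model["start"] <= pos0) & (pos0 < model["end"])
        ]
        for _, f in feat.iterrows():
            if f["type"] == "exon":
                consider("exonic")
            elif f["type"] == "UTR":
                consider("UTR")
            elif f["type"] == "gene":
                consider("intronic")
        for _, g in genes.loc[genes["chrom"] == v["chrom"]].iterrows():
            if g["start"] <= pos0 < g["end"]:
                continue
            before = g["start"] - flank_bp <= pos0 < g["start"]
            after = g["end"] <= pos0 < g["end"] + flank_bp
            if g["strand"] == "-":
                before, after = after, before
            if before:
                consider("upstream")
            elif after:
                consider("downstream")
        labels.append(best)
    return pd.Series(labels, index=variants.index, name="region")


# ---------------------------------------------------------------------------
# enhancer colocalization
# ---------------------------------------------------------------------------


def read_bed_enhancers(path, kind: str | None = None) -> pd.DataFrame:
    """BED enhancer intervals; the kind (SE/TE) comes from column 4 unless
    given per-file."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    out = pd.DataFrame({"chrom": df[0], "start": df[1].astype(int), "end": df[2].astype(int)})
    if kind is not None:
        out["kind"] = kind
    elif df.shape[1] >= 4:
        out["kind"] = df[3]
    else:
        raise VariantError("enhancer kind missing: provide BED column 4 or kind=")
    bad = set(out["kind"]) - {"SE", "TE"}
    if bad:
        raise VariantError(f"enhancer kind must be SE or TE, got {sorted(bad)}")
    return out


def mcnemar_exact_p(b: int, c: int) -> float:
    """Two-sided exact McNemar p on discordant counts:
    min(1, 2 * P(X <= min(b, c))), X ~ Binomial(b + c, 1/2)."""
    if b < 0 or c < 0:
        raise VariantError("discordant counts must be non-negative")
    n = b + c
    if n == 0:
        return 1.0
    return float(min(1.0, 2.0 * stats.binom.cdf(min(b, c), n, 0.5)))


def enhancer_colocalize(
    variants: pd.DataFrame, enhancers: pd.DataFrame
) -> tuple[pd.DataFrame, dict]:
    """Flag each variant for SE/TE overlap and summarize.

    A variant at 1-based pos overlaps a 0-based half-open interval when
    pos - 1 in [start, end).  Summary counts n_SE_only / n_TE_only / n_both /
    n_neither, percentages of the total to 1 decimal, and the exact McNemar
    two-sided p on the discordant counts.
    """
    if len(variants) == 0:
        raise VariantError("empty variant set")
    se = enhancers.loc[enhancers["kind"] == "SE"]
    te = enhancers.loc[enhancers["kind"] == "TE"]

    def _in(iv: pd.DataFrame, chrom, pos0) -> bool:
        sub = iv.loc[iv["chrom"] == chrom]
        return bool(((sub["start"] <= pos0) & (pos0 < sub["end"])).any())

    flags = variants.copy()
    flags["in_SE"] = [
        _in(se, v["chrom"], int(v["pos"]) - 1) for _, v in variants.iterrows()
    ]
    flags["in_TE"] = [
        _in(te, v["chrom"], int(v["pos"]) - 1) for _, v in variants.iterrows()
    ]
    n = len(flags)
    b = int((flags["in_SE"] & ~flags["in_TE"]).sum())
    c = int((~flags["in_SE"] & flags["in_TE"]).sum())
    both = int((flags["in_SE"] & flags["in_TE"]).sum())
    neither = n - b - c - both
    summary = {
        "n_total": n,
        "n_SE_only": b,
        "n_TE_only": c,
        "n_both": both,
        "n_neither": neither,
        "pct_SE_only": round(100.0 * b / n, 1),
        "pct_TE_only": round(100.0 * c / n, 1),
        "pct_both": round(100.0 * both / n, 1),
        "pct_neither": round(100.0 * neither / n, 1),
        "mcnemar_p": mcnemar_exact_p(b, c),
    }
    return flags, summary


# ---------------------------------------------------------------------------
# PWM allele scoring
# ---------------------------------------------------------------------------

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


class Pwm:
    """Position frequency matrix with log2-odds scoring.

    ``matrix`` is a 4 x L array of counts or frequencies in A, C, G, T row
    order.  Columns are renormalized with the pseudocount:
    f = (m + pc) / (colsum + 4 pc); score contribution log2(f / background).
    """

    def __init__(self, motif_id: str, matrix, pseudocount: float = 0.01, background=None):
        self.motif_id = motif_id
        m = np.asarray(matrix, dtype=float)
        if m.shape[0] != 4:
            raise VariantError("PWM matrix must have 4 rows (A, C, G, T)")
        if np.any(m < 0):
            raise VariantError("PWM entries must be non-negative")
        self.pseudocount = float(pseudocount)
        bg = np.asarray(background if background is not None else [0.25] * 4, dtype=float)
        if bg.shape != (4,) or not math.isclose(bg.sum(), 1.0, rel_tol=1e-6):
            raise VariantError("background must be 4 probabilities summing to 1")
        self.background = bg
        col_sums = m.sum(axis=0)
        if np.any(col_sums + 4 * self.pseudocount <= 0):
            raise VariantError("PWM column sums to zero with zero pseudocount")
        self.freq = (m + self.pseudocount) / (col_sums + 4 * self.pseudocount)[None, :]
        with np.errstate(divide="ignore"):
            self.logodds = np.log2(self.freq / bg[:, None])

    @property
    def length(self) -> int:
        return self.logodds.shape[1]

    def score(self, seq: str) -> float:
        seq = seq.upper()
        if len(seq) != self.length:
            raise VariantError("sequence length must equal motif length")
        return float(sum(self.logodds[_BASE_INDEX[b], j] for j, b in enumerate(seq)))

    @classmethod
    def from_jaspar(cls, path, pseudocount: float = 0.01, background=None) -> "Pwm":
        from Bio import motifs

        with open(path) as fh:
            motif = motifs.read(fh, "jaspar")
        m = np.array([motif.counts[b] for b in "ACGT"], dtype=float)
        return cls(motif.matrix_id or motif.name or "motif", m, pseudocount, background)


def _revcomp(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


def pwm_allele_score(
    pwm: Pwm, window: str, variant_offset: int, ref: str, alt: str
) -> tuple[float, float, float]:
    """Score the reference and alternate allele at the best motif placement.

    All placements (offset x strand) that cover the variant are scored on the
    reference window; the maximizer is fixed and the alternate allele is
    scored at that same placement.  Returns (score_ref, score_alt, delta)
    in log2-odds bits; delta = score_alt - score_ref.
    """
    window = window.upper()
    ref, alt = ref.upper(), alt.upper()
    L = pwm.length
    if len(window) < L:
        raise VariantError("window shorter than motif")
    if not 0 <= variant_offset < len(window):
        raise VariantError("variant offset outside window")
    if window[variant_offset] != ref:
        raise VariantError(
            f"window base {window[variant_offset]!r} at offset {variant_offset} "
            f"disagrees with ref allele {ref!r}"
        )
    alt_window = window[:variant_offset] + alt + window[variant_offset + 1 :]

    best = None
    for o in range(len(window) - L + 1):
        if not o <= variant_offset < o + L:
            continue
        for strand in ("+", "-"):
            sub = window[o : o + L]
            s = pwm.score(sub if strand == "+" else _revcomp(sub))
            if best is None or s > best[0] + 1e-12:
                best = (s, o, strand)
    if best is None:
        raise VariantError("no motif placement covers the variant")
    score_ref, o, strand = best
    sub_alt = alt_window[o : o + L]
    score_alt = pwm.score(sub_alt if strand == "+" else _revcomp(sub_alt))
    return score_ref, score_alt, score_alt - score_ref


# ---------------------------------------------------------------------------
# expression correlation
# ---------------------------------------------------------------------------


def correlate_expression(x, y, method: str = "spearman") -> tuple[float, float]:
    """Spearman rank correlation with midrank ties.

    Exact permutation p for n <= 9 without ties; t-approximation otherwise.
    Constant input is undefined: returns (nan, nan) with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if method != "spearman":
        raise VariantError(f"unsupported method {method!r}")
    if x.size != y.size or x.size < 3:
        raise VariantError("need two equal-length vectors with n >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        warnings.warn("constant vector: correlation undefined")
        return float("nan"), float("nan")
    rho, p_approx = stats.spearmanr(x, y)
    n = x.size
    no_ties = len(set(x)) == n and len(set(y)) == n
    if n <= 9 and no_ties:
        rx = stats.rankdata(x)
        obs = abs(rho)
        count = 0
        total = 0
        for perm in itertools.permutations(stats.rankdata(y)):
            r = np.corrcoef(rx, perm)[0, 1]
            count += abs(r) >= obs - 1e-12
            total += 1
        return float(rho), count / total
    return float(rho), float(p_approx)


# ---------------------------------------------------------------------------
# eGene x DEG intersection
# ---------------------------------------------------------------------------


def intersect_degs(
    egenes,
    results: dict[tuple[str, str, str], pd.DataFrame],
    p_max: float = 0.05,
    fc_min: float = 1.5,
) -> tuple[list[str], pd.DataFrame, dict[str, int]]:
    """Intersect an eGene set with nominal differential expression events.

    An event is one (gene, contrast) pair with p < p_max and
    |log2fc| >= log2(fc_min) for a gene in the eGene set.  Returns
    (sorted overlapping genes, event table, event counts per family).
    """
    egenes = set(egenes)
    log2_fc_min = math.log2(fc_min)
    rows = []
    for (family, a, b), df in results.items():
        hit = df.loc[
            df["gene_id"].isin(egenes)
            & (df["p"] < p_max)
            & (df["log2fc"].abs() >= log2_fc_min)
        ]
        for _, r in hit.iterrows():
            rows.append(
                {"gene_id": r["gene_id"], "family": family, "area_a": a, "area_b": b,
                 "log2fc": r["log2fc"], "p": r["p"]}
            )
    events = pd.DataFrame(rows, columns=["gene_id", "family", "area_a", "area_b", "log2fc", "p"])
    genes = sorted(events["gene_id"].unique()) if len(events) else []
    counts = {fam: int((events["family"] == fam).sum()) for fam in ("LR", "WH_L", "WH_R")}
    return genes, events, counts
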