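"""Donor-paired differential expression with multi-level FDR control.

Contrast families:

* ``LR``   — right vs left hemisphere within one Brodmann area (log2FC > 0
  means higher on the right);
* ``WH_L`` / ``WH_R`` — area A vs area B within the left / right hemisphere
  (log2FC > 0 means higher in area A).

Each contrast is restricted to donors contributing both conditions (at least
two), filtered (subset total count >= 10 and nonzero in >= 3 samples),
TMM-normalized within the subset, and fit with a donor-blocked linear model.

Engines:

* ``moderated_t`` (default): per-gene weighted least squares on log2-CPM with
  inverse-variance precision weights from a fitted mean-variance trend, and
  empirical-Bayes shrinkage of residual variances toward a common prior
  (posterior variance = (d0*s0^2 + d*s^2)/(d0 + d), t on d0 + d df).
* ``nb_wald``: per-gene negative-binomial log-link GLM with library-size
  offsets, gene-wise moment dispersions shrunk toward a mean-dispersion
  trend, Wald z on the condition coefficient, no outlier filtering.

Multiple testing is controlled at four levels (all Benjamini-Hochberg):
within contrast, globally over all genes x contrasts, within contrast family,
and within the functional module shared by a contrast's areas ("mixed" pairs
spanning two modules are not adjusted at the module level).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .expression_io import CountMatrix, log_cpm, tmm_factors

FAMILIES = ("LR", "WH_L", "WH_R")

NUMERIC_COVARIATES = ("age",)
COVARIATES = ("sex", "age", "handedness", "family_history", "language_disorder")

#: six functional modules of the speech-processing cortex
DEFAULT_MODULE_MAP = {
    "BA44": "Broca",
    "BA45": "Broca",
    "BA22": "Wernicke",
    "BA21": "Wernicke",
    "BA39": "Geschwind",
    "BA40": "Geschwind",
    "BA41": "primary auditory",
    "BA42": "primary auditory",
    "BA6": "ventral sensorimotor",
    "BA4": "ventral sensorimotor",
    "BA3/1/2": "ventral sensorimotor",
    "BA9": "other",
    "BA37": "other",
}


class ContrastError(ValueError):
    """Raised for invalid contrast construction or rank-deficient designs."""


# ---------------------------------------------------------------------------
# contrast construction
# ---------------------------------------------------------------------------


@dataclass
class ContrastSpec:
    """One donor-paired contrast plus its covariate ledger.

    ``samples_a`` is the numerator condition (R hemisphere for LR; area_a for
    WH) and ``samples_b`` the reference, per donor order in ``donors_used``.
    ``covariate_ledger`` maps covariate -> dict(included, reason, imputed).
    """

    family: str
    area_a: str
    area_b: str
    donors_used: list[str]
    samples_a: list[str]
    samples_b: list[str]
    covariate_ledger: dict = field(default_factory=dict)
    covariate_values: pd.DataFrame | None = None

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.family, self.area_a, self.area_b)

    @property
    def samples(self) -> list[str]:
        return list(self.samples_a) + list(self.samples_b)


def build_contrast(
    meta: pd.DataFrame, family: str, area_a: str, area_b: str | None = None
) -> ContrastSpec:
    """Assemble a donor-paired contrast from the sample metadata.

    Donors lacking either condition are dropped; fewer than two remaining
    donors is an error.  Donor-level covariates are admitted only when they
    vary among the donors used (constant or all-missing covariates are
    excluded, with the reason recorded); numeric covariates are median-imputed
    and categorical covariates mode-imputed, with imputed values recorded.
    """
    if family not in FAMILIES:
        raise ContrastError(f"unknown family {family!r}")
    if family == "LR":
        area_b = area_a if area_b is None else area_b
        if area_b != area_a:
            raise ContrastError("LR contrasts compare hemispheres within one area")
        sel_a = (meta["area"] == area_a) & (meta["hemisphere"] == "R")
        sel_b = (meta["area"] == area_a) & (meta["hemisphere"] == "L")
    else:
        if area_b is None:
            raise ContrastError("WH contrasts need two areas")
        hemi = "L" if family == "WH_L" else "R"
        sel_a = (meta["area"] == area_a) & (meta["hemisphere"] == hemi)
        sel_b = (meta["area"] == area_b) & (meta["hemisphere"] == hemi)
    for label, area in (("area_a", area_a), ("area_b", area_b)):
        if area not in set(meta["area"]):
            raise ContrastError(f"{label}={area!r} not present in metadata")

    a_by_donor = meta.loc[sel_a].set_index("donor")["sample_id"]
    b_by_donor = meta.loc[sel_b].set_index("donor")["sample_id"]
    donors = [d for d in a_by_donor.index if d in set(b_by_donor.index)]
    if len(donors) < 2:
        raise ContrastError(
            f"contrast {family} {area_a} vs {area_b}: only {len(donors)} donor(s) "
            "contribute both conditions (need >= 2)"
        )

    donor_meta = (
        meta.loc[meta["donor"].isin(donors), ["donor", *COVARIATES]]
        .drop_duplicates("donor")
        .set_index("donor")
        .loc[donors]
    )
    ledger: dict[str, dict] = {}
    values = {}
    for cov in COVARIATES:
        col = donor_meta[cov]
        if col.isna().all():
            ledger[cov] = {"included": False, "reason": "all-missing", "imputed": None}
            continue
        imputed = None
        if col.isna().any():
            if cov in NUMERIC_COVARIATES:
                imputed = float(col.median())
            else:
                imputed = col.mode().iloc[0]
            col = col.fillna(imputed)
        if col.nunique() <= 1:
            ledger[cov] = {"included": False, "reason": "constant", "imputed": imputed}
            continue
        ledger[cov] = {"included": True, "reason": None, "imputed": imputed}
        values[cov] = col
    cov_values = pd.DataFrame(values, index=donors) if values else None

    return ContrastSpec(
        family=family,
        area_a=area_a,
        area_b=area_b,
        donors_used=donors,
        samples_a=[a_by_donor[d] for d in donors],
        samples_b=[b_by_donor[d] for d in donors],
        covariate_ledger=ledger,
        covariate_values=cov_values,
    )


def filter_genes(cm: CountMatrix, spec: ContrastSpec) -> np.ndarray:
    """Boolean mask of genes kept for this contrast's sample subset:
    total count >= 10 and nonzero in >= 3 subset samples."""
    sub = cm.subset_samples(spec.samples)
    total = sub.counts.sum(axis=1)
    nonzero = (sub.counts > 0).sum(axis=1)
    return (total >= 10) & (nonzero >= 3)


# ---------------------------------------------------------------------------
# design matrix
# ---------------------------------------------------------------------------


def _standardize_numeric(x: np.ndarray) -> np.ndarray:
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    scale = 1.4826 * mad
    if scale == 0:
        scale = np.std(x, ddof=1)
    if scale == 0:
        scale = 1.0
    return (x - med) / scale


def build_design(spec: ContrastSpec, on_aliased: str = "drop") -> tuple[np.ndarray, list[str]]:
    """Design matrix: intercept + donor blocks + condition + admitted covariates.

    Donor-level covariates are linear combinations of the donor dummies, so
    they are aliased in a donor-blocked design.  ``on_aliased="drop"``
    removes such columns and records them in the covariate ledger;
    ``"error"`` raises listing the aliased columns.
    """
    donors = spec.donors_used
    n = 2 * len(donors)
    cols: list[np.ndarray] = [np.ones(n)]
    names = ["intercept"]
    for d in donors[1:]:
        v = np.zeros(n)
        i = donors.index(d)
        v[i] = v[i + len(donors)] = 1.0
        cols.append(v)
        names.append(f"donor_{d}")
    cond = np.concatenate([np.ones(len(donors)), np.zeros(len(donors))])
    cols.append(cond)
    names.append("condition")
    if spec.covariate_values is not None:
        for cov in spec.covariate_values.columns:
            col = spec.covariate_values[cov]
            if cov in NUMERIC_COVARIATES:
                x = _standardize_numeric(col.to_numpy(dtype=float))
                cols.append(np.tile(x, 2))
                names.append(cov)
            else:
                levels = sorted(col.unique())
                for lev in levels[1:]:
                    cols.append(np.tile((col == lev).to_numpy(float), 2))
                    names.append(f"{cov}_{lev}")
    X = np.column_stack(cols)

    # detect aliased columns by incremental rank
    keep = []
    rank = 0
    aliased = []
    for j in range(X.shape[1]):
        r = np.linalg.matrix_rank(X[:, keep + [j]])
        if r > rank:
            keep.append(j)
            rank = r
        else:
            aliased.append(names[j])
    if aliased:
        if "condition" in aliased:
            raise ContrastError("condition term aliased by the design")
        if on_aliased == "error":
            raise ContrastError(f"design not full rank; aliased columns: {aliased}")
        for name in aliased:
            cov = name.split("_")[0]
            if cov in spec.covariate_ledger:
                spec.covariate_ledger[cov] = {
                    "included": False,
                    "reason": "aliased_with_donor",
                    "imputed": spec.covariate_ledger[cov].get("imputed"),
                }
        X = X[:, keep]
        names = [names[j] for j in keep]
    return X, names


# ---------------------------------------------------------------------------
# moderated-t engine
# ---------------------------------------------------------------------------


def _trigamma_inverse(x: float) -> float:
    if x <= 0:
        return np.inf
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y = y + dif
        if abs(dif) < 1e-8 * y:
            break
    return float(y)


def fit_f_dist(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment fit of a scaled F prior to sample variances (empirical Bayes).

    Returns (d0, s0^2): prior degrees of freedom (may be inf) and prior
    variance, via the moments of log s^2.
    """
    s2 = np.asarray(s2, dtype=float)
    ok = np.isfinite(s2) & (s2 > 0)
    if ok.sum() < 2:
        return np.inf, float(np.nanmedian(s2[ok])) if ok.any() else 1.0
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = float(np.mean(e))
    e_var = float(np.var(e, ddof=1)) - float(special.polygamma(1, df / 2.0))
    if e_var <= 0:
        d0 = np.inf
        s0_2 = float(np.exp(e_mean))
    else:
        d0 = 2.0 * _trigamma_inverse(e_var)
        s0_2 = float(np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s0_2


def _mean_variance_trend(mean_lcpm: np.ndarray, resid_sd: np.ndarray, n_bins: int = 10):
    """Binned running median of residual sd vs mean log-CPM, linearly
    interpolated; returns a callable sd predictor."""
    ok = np.isfinite(mean_lcpm) & np.isfinite(resid_sd)
    x, y = mean_lcpm[ok], resid_sd[ok]
    if x.size < 2 * n_bins:
        n_bins = max(2, x.size // 2) or 2
    order = np.argsort(x)
    xs, ys = x[order], y[order]
    edges = np.array_split(np.arange(xs.size), n_bins)
    centers = np.array([xs[idx].mean() for idx in edges if idx.size])
    medians = np.array([np.median(ys[idx]) for idx in edges if idx.size])
    floor = max(1e-4, float(np.min(medians[medians > 0], initial=1e-4)))

    def predict(v: np.ndarray) -> np.ndarray:
        out = np.interp(v, centers, medians)
        # linear extrapolation beyond the outermost bin centers: the variance
        # rises steeply at the lowest counts and flat clamping would
        # under-predict it there
        if len(centers) >= 2:
            lo = v < centers[0]
            slope_lo = (medians[1] - medians[0]) / (centers[1] - centers[0])
            out = np.where(lo, medians[0] + slope_lo * (v - centers[0]), out)
            hi = v > centers[-1]
            slope_hi = (medians[-1] - medians[-2]) / (centers[-1] - centers[-2])
            out = np.where(hi, medians[-1] + slope_hi * (v - centers[-1]), out)
        return np.maximum(out, floor)

    return predict


def _weighted_fit(Y: np.ndarray, X: np.ndarray, W: np.ndarray, cond_idx: int):
    """Per-gene weighted least squares.  Y genes x samples, W same shape.
    Returns (coef, stdev_unscaled, sigma, df_resid)."""
    G, n = Y.shape
    p = X.shape[1]
    df = n - p
    coef = np.empty(G)
    unscaled = np.empty(G)
    sigma = np.empty(G)
    for g in range(G):
        w = W[g]
        sw = np.sqrt(w)
        Xw = X * sw[:, None]
        yw = Y[g] * sw
        beta, res, rank, _ = np.linalg.lstsq(Xw, yw, rcond=None)
        fitted = Xw @ beta
        rss = float(np.sum((yw - fitted) ** 2))
        xtx_inv = np.linalg.pinv(Xw.T @ Xw)
        coef[g] = beta[cond_idx]
        unscaled[g] = np.sqrt(max(xtx_inv[cond_idx, cond_idx], 0.0))
        sigma[g] = np.sqrt(rss / df) if df > 0 else np.nan
    return coef, unscaled, sigma, df


def _fit_moderated_t(
    cm: CountMatrix, spec: ContrastSpec, X: np.ndarray, genes_kept: np.ndarray,
    eb: bool = True, prior_df: float | None = None, precision_weights: bool = True,
) -> pd.DataFrame:
    sub = cm.subset_samples(spec.samples)
    kept_ids = [g for g, k in zip(sub.gene_ids, genes_kept) if k]
    sub = CountMatrix(kept_ids, sub.sample_ids, sub.counts[genes_kept])
    factors = tmm_factors(sub)
    lcpm = log_cpm(sub, factors).values
    cond_idx = 1 + (len(spec.donors_used) - 1)  # intercept + donor dummies

    n, p = X.shape
    df = n - p
    if df <= 0:
        raise ContrastError("no residual degrees of freedom")

    # first pass: unweighted fit for the mean-variance trend
    beta1, _, _, _ = np.linalg.lstsq(X, lcpm.T, rcond=None)
    fitted1 = (X @ beta1).T
    resid1 = lcpm - fitted1
    sd1 = np.sqrt(np.sum(resid1**2, axis=1) / df)
    if precision_weights:
        mean_lcpm = lcpm.mean(axis=1)
        trend = _mean_variance_trend(mean_lcpm, sd1)
        W = 1.0 / trend(fitted1) ** 2  # per-observation precision weights
    else:
        W = np.ones_like(lcpm)

    coef, unscaled, sigma, df = _weighted_fit(lcpm, X, W, cond_idx)

    # degenerate when residual sd vanishes relative to the data scale
    y_rms = np.sqrt(np.mean(lcpm**2, axis=1))
    rel_sigma = sigma / np.sqrt(W.mean(axis=1)) / (y_rms + 1.0)
    zero_var = ~np.isfinite(sigma) | (rel_sigma < 1e-9)
    s2 = np.where(zero_var, np.nan, sigma**2)

    if prior_df is not None:
        d0 = float(prior_df)
        _, s0_2 = fit_f_dist(s2[~zero_var], df)
    elif eb:
        d0, s0_2 = fit_f_dist(s2[~zero_var], df)
    else:
        d0, s0_2 = 0.0, 1.0

    if d0 == 0:
        post_var = s2
        df_total = float(df)
    elif np.isinf(d0):
        post_var = np.full_like(s2, s0_2)
        df_total = 1e8
    else:
        post_var = (d0 * s0_2 + df * s2) / (d0 + df)
        df_total = float(d0 + df)

    se = unscaled * np.sqrt(post_var)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = coef / se
    pvals = 2.0 * stats.t.sf(np.abs(t), df_total)
    flagged = zero_var | ~np.isfinite(pvals)
    t = np.where(flagged, 0.0, t)
    pvals = np.where(flagged, 1.0, pvals)

    return pd.DataFrame(
        {
            "gene_id": kept_ids,
            "log2fc": coef,
            "statistic": t,
            "p": pvals,
            "flag_degenerate": flagged,
        }
    )


# ---------------------------------------------------------------------------
# negative-binomial Wald engine
# ---------------------------------------------------------------------------


def _fit_nb_wald(
    cm: CountMatrix, spec: ContrastSpec, X: np.ndarray, genes_kept: np.ndarray,
    dispersion_prior_weight: float = 3.0,
) -> pd.DataFrame:
    import statsmodels.api as sm

    sub = cm.subset_samples(spec.samples)
    kept_ids = [g for g, k in zip(sub.gene_ids, genes_kept) if k]
    Y = sub.counts[genes_kept].astype(float)
    factors = tmm_factors(CountMatrix(kept_ids, sub.sample_ids, Y.astype(np.int64)))
    eff = Y.sum(axis=0) * factors
    offset = np.log(eff / np.exp(np.mean(np.log(eff))))
    cond_idx = 1 + (len(spec.donors_used) - 1)
    n, p = X.shape
    df = n - p

    # moment dispersions on offset-normalized counts
    norm = Y / np.exp(offset)[None, :]
    mu_hat = norm.mean(axis=1)
    var_hat = norm.var(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        raw_disp = np.clip((var_hat - mu_hat) / mu_hat**2, 1e-8, 10.0)
    order = np.argsort(mu_hat)
    n_bins = max(2, min(10, len(kept_ids) // 5)) or 2
    groups = np.array_split(order, n_bins)
    centers = np.array([mu_hat[g].mean() for g in groups if g.size])
    med = np.array([np.median(raw_disp[g]) for g in groups if g.size])
    trend = np.maximum(np.interp(mu_hat, centers, med), 1e-8)
    w0 = dispersion_prior_weight
    disp = np.exp((np.log(raw_disp) + w0 * np.log(trend)) / (1.0 + w0))

    coef = np.zeros(len(kept_ids))
    z = np.zeros(len(kept_ids))
    pvals = np.ones(len(kept_ids))
    flags = np.zeros(len(kept_ids), dtype=bool)
    ln2 = np.log(2.0)
    for g in range(len(kept_ids)):
        y = Y[g]
        if df <= 0 or np.all(y == y[0]):
            flags[g] = True
            continue
        try:
            model = sm.GLM(
                y, X, family=sm.families.NegativeBinomial(alpha=float(disp[g])), offset=offset
            )
            res = model.fit(maxiter=100)
            coef[g] = res.params[cond_idx] / ln2
            se = res.bse[cond_idx]
            if not np.isfinite(se) or se == 0:
                flags[g] = True
                continue
            z[g] = res.params[cond_idx] / se
            pvals[g] = 2.0 * stats.norm.sf(abs(z[g]))
        except Exception:
            flags[g] = True
    pvals = np.where(flags, 1.0, pvals)
    return pd.DataFrame(
        {"gene_id": kept_ids, "log2fc": coef, "statistic": z, "p": pvals,
         "flag_degenerate": flags}
    )


def fit_contrast(
    cm: CountMatrix,
    spec: ContrastSpec,
    engine: str = "moderated_t",
    on_aliased: str = "drop",
    **engine_kwargs,
) -> pd.DataFrame:
    """Fit one donor-paired contrast; returns gene_id, log2fc, statistic, p."""
    genes_kept = filter_genes(cm, spec)
    if genes_kept.sum() == 0:
        raise ContrastError("no genes pass the expression filter")
    X, _names = build_design(spec, on_aliased=on_aliased)
    if engine == "moderated_t":
        return _fit_moderated_t(cm, spec, X, genes_kept, **engine_kwargs)
    if engine == "nb_wald":
        return _fit_nb_wald(cm, spec, X, genes_kept, **engine_kwargs)
    raise ContrastError(f"unknown engine {engine!r}")


# ---------------------------------------------------------------------------
# multi-level FDR
# ---------------------------------------------------------------------------


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (step-up)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def adjust_multilevel(
    results: dict[tuple[str, str, str], pd.DataFrame],
    module_map: dict[str, str] | None = None,
) -> dict[tuple[str, str, str], pd.DataFrame]:
    """Add q_contrast, q_global, q_family, module_label and q_module columns.

    ``results`` maps (family, area_a, area_b) -> fit_contrast output.
    q_family pools p-values within each contrast family (LR across areas,
    WH_L, WH_R); q_module pools within the functional module shared by a
    contrast's areas; pairs spanning two modules are labeled "mixed" and get
    no module-level adjustment.
    """
    module_map = DEFAULT_MODULE_MAP if module_map is None else module_map
    out = {k: df.copy() for k, df in results.items()}

    for key, df in out.items():
        family, area_a, area_b = key
        for area in (area_a, area_b):
            if area not in module_map:
                raise ContrastError(f"area {area!r} not in module map")
        df["q_contrast"] = bh_adjust(df["p"].to_numpy())
        mod_a, mod_b = module_map[area_a], module_map[area_b]
        df["module_label"] = mod_a if mod_a == mod_b else "mixed"

    def pooled(keys: list, col: str) -> None:
        if not keys:
            return
        lens = [len(out[k]) for k in keys]
        allp = np.concatenate([out[k]["p"].to_numpy() for k in keys])
        q = bh_adjust(allp)
        start = 0
        for k, ln in zip(keys, lens):
            out[k][col] = q[start : start + ln]
            start += ln

    pooled(list(out.keys()), "q_global")
    for family in FAMILIES:
        pooled([k for k in out if k[0] == family], "q_family")
    modules = {df["module_label"].iloc[0] for df in out.values() if len(df)}
    for df in out.values():
        df["q_module"] = np.nan
    for mod in modules - {"mixed"}:
        keys = [k for k in out if len(out[k]) and out[k]["module_label"].iloc[0] == mod]
        if not keys:
            continue
        allp = np.concatenate([out[k]["p"].to_numpy() for k in keys])
        q = bh_adjust(allp)
        start = 0
        for k in keys:
            ln = len(out[k])
            out[k]["q_module"] = q[start : start + ln]
            start += ln
    return out


def run_all_contrasts(
    cm: CountMatrix,
    meta: pd.DataFrame,
    families: tuple[str, ...] = FAMILIES,
    engine: str = "moderated_t",
    module_map: dict[str, str] | None = None,
    **engine_kwargs,
) -> dict[tuple[str, str, str], pd.DataFrame]:
    """Fit every feasible contrast in the requested families and adjust.

    LR: one contrast per area.  WH: every unordered area pair per hemisphere.
    Contrasts lacking two paired donors are skipped with a warning.
    """
    areas = sorted(meta["area"].unique())
    raw: dict[tuple[str, str, str], pd.DataFrame] = {}
    specs: list[ContrastSpec] = []
    if "LR" in families:
        specs += [("LR", a, a) for a in areas]
    for fam in ("WH_L", "WH_R"):
        if fam in families:
            specs += [
                (fam, a, b) for i, a in enumerate(areas) for b in areas[i + 1 :]
            ]
    for family, a, b in specs:
        try:
            spec = build_contrast(meta, family, a, b)
        except ContrastError as exc:
            warnings.warn(f"skipping {family} {a} vs {b}: {exc}")
            continue
        raw[spec.key] = fit_contrast(cm, spec, engine=engine, **engine_kwargs)
    if not raw:
        raise ContrastError("no feasible contrasts in the requested families")
    return adjust_multilevel(raw, module_map=module_map)


def write_results(results: dict, out_dir) -> None:
    """One TSV per contrast with all statistic and q columns."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for (family, a, b), df in sorted(results.items()):
        safe = f"{family}_{a}_vs_{b}".replace("/", "-")
        df.to_csv(out / f"{safe}.tsv", sep="\t", index=False, float_format="%.10g")
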