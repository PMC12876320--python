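"""Synthetic inputs with known ground truth for every pipeline stage.

Three generators:

* donor-paired bilateral expression counts (negative binomial with log-link
  donor / area / hemisphere-by-area effects, log-normal library sizes);
* haplotype panels with block LD structure, plus toy GWAS / cis-eQTL /
  enhancer resources with known overlap structure;
* ultrasonic-vocalization audio (tones, linear chirps, sinusoidal FM, white
  noise floor) with an analytic ground-truth segment table.

Everything is driven by a ``numpy.random.default_rng`` seed: a fixed seed
yields byte-identical output.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .expression_io import CountMatrix, META_COLUMNS

BRAIN_TISSUES = [
    "Amygdala",
    "Anterior_cingulate_cortex",
    "Caudate",
    "Cerebellar_hemisphere",
    "Cerebellum",
    "Cortex",
    "Frontal_cortex",
    "Hippocampus",
    "Hypothalamus",
    "Nucleus_accumbens",
    "Putamen",
    "Spinal_cord",
    "Substantia_nigra",
]


class SimSpecError(ValueError):
    """Raised when a simulation spec violates its invariants."""


# ---------------------------------------------------------------------------
# donor-paired bilateral expression
# ---------------------------------------------------------------------------


@dataclass
class ExpressionSimSpec:
    """Design of a donor-paired bilateral count simulation.

    ``lateralized_genes`` maps gene -> (area, log2 effect): the gene's right-
    hemisphere mean in that area is multiplied by 2**effect.
    ``handedness_linked_genes`` maps gene -> (area, log2 effect): the right-
    hemisphere bias is applied to right-handed donors only (left-handed
    donors carry no effect), emulating handedness-coupled lateralization for
    the leave-one-donor-out analysis.
    ``missing`` lists (donor, hemisphere, area) samples to drop, so incomplete
    designs (e.g. 125 of 130 possible samples) can be emulated.
    """

    n_genes: int
    n_donors: int
    areas: list[str]
    baseline_mean: float = 100.0
    dispersion: float = 0.1
    dispersion_sd: float = 0.3  # log-scale spread of per-gene dispersions
    lateralized_genes: dict = field(default_factory=dict)
    handedness_linked_genes: dict = field(default_factory=dict)
    donor_sd: float = 0.1
    gene_sd: float = 1.0
    libsize_sd: float = 0.2
    covariates: pd.DataFrame | None = None
    missing: list = field(default_factory=list)
    seed: int = 0

    def gene_ids(self) -> list[str]:
        return [f"gene{i + 1:05d}" for i in range(self.n_genes)]

    def donor_ids(self) -> list[str]:
        return [f"D{i + 1}" for i in range(self.n_donors)]

    def validate(self) -> None:
        if self.n_genes < 1:
            raise SimSpecError("n_genes must be >= 1")
        if self.n_donors < 1:
            raise SimSpecError("n_donors must be >= 1")
        if not self.areas:
            raise SimSpecError("areas must be non-empty")
        if self.baseline_mean <= 0:
            raise SimSpecError("baseline_mean must be positive")
        if self.dispersion < 0:
            raise SimSpecError("dispersion must be >= 0")
        if self.donor_sd < 0:
            raise SimSpecError("donor_sd must be >= 0")
        if self.dispersion_sd < 0:
            raise SimSpecError("dispersion_sd must be >= 0")
        genes = set(self.gene_ids())
        for table_name, table in (
            ("lateralized_genes", self.lateralized_genes),
            ("handedness_linked_genes", self.handedness_linked_genes),
        ):
            for g, (area, _eff) in table.items():
                if g not in genes:
                    raise SimSpecError(f"{table_name}: {g} not in gene universe")
                if area not in self.areas:
                    raise SimSpecError(f"{table_name}: area {area} not in areas")
        donors = set(self.donor_ids())
        for d, h, a in self.missing:
            if d not in donors or h not in ("L", "R") or a not in self.areas:
                raise SimSpecError(f"missing: invalid entry {(d, h, a)}")


def _default_covariates(spec: ExpressionSimSpec, rng: np.random.Generator) -> pd.DataFrame:
    donors = spec.donor_ids()
    return pd.DataFrame(
        {
            "donor": donors,
            "sex": [("M", "F")[i % 2] for i in range(len(donors))],
            "age": rng.integers(63, 88, size=len(donors)),
            "handedness": ["R"] * len(donors),
            "family_history": ["no"] * len(donors),
            "language_disorder": ["no"] * len(donors),
        }
    )


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, dispersion) -> np.ndarray:
    """Negative binomial with var = mu + dispersion * mu**2 (Poisson at 0).
    ``dispersion`` may be per-gene."""
    dispersion = np.asarray(dispersion, dtype=float)
    if np.all(dispersion == 0):
        return rng.poisson(mu)
    size = 1.0 / np.maximum(dispersion, 1e-12)
    p = size / (size + mu)
    out = rng.negative_binomial(size, p)
    if np.any(dispersion == 0):
        zero = dispersion == 0
        out[zero] = rng.poisson(mu[zero] if mu.ndim else mu)
    return out


def simulate_expression(
    spec: ExpressionSimSpec,
) -> tuple[CountMatrix, pd.DataFrame, pd.DataFrame]:
    """Simulate donor-paired bilateral counts.

    Returns (counts, sample metadata, truth table).  The truth table has one
    row per injected effect: gene, area, log2fc, kind in
    {lateralized, handedness_linked}.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    genes = spec.gene_ids()
    donors = spec.donor_ids()

    covs = spec.covariates if spec.covariates is not None else _default_covariates(spec, rng)
    covs = covs.set_index("donor", drop=False)

    donor_eff = rng.normal(0.0, spec.donor_sd, size=len(donors))
    gene_eff = rng.normal(0.0, spec.gene_sd, size=len(genes))
    if spec.dispersion > 0 and spec.dispersion_sd > 0:
        # gene-specific dispersions, log-normal around the base value
        gene_disp = spec.dispersion * np.exp(
            rng.normal(0.0, spec.dispersion_sd, size=len(genes))
            - spec.dispersion_sd**2 / 2.0
        )
    else:
        gene_disp = np.full(len(genes), spec.dispersion)

    lat = np.zeros((len(genes), len(spec.areas)))
    gene_index = {g: i for i, g in enumerate(genes)}
    area_index = {a: j for j, a in enumerate(spec.areas)}
    truth_rows = []
    for g, (area, eff) in spec.lateralized_genes.items():
        lat[gene_index[g], area_index[area]] = eff
        truth_rows.append({"gene_id": g, "area": area, "log2fc": eff, "kind": "lateralized"})
    hand = np.zeros((len(genes), len(spec.areas)))
    for g, (area, eff) in spec.handedness_linked_genes.items():
        hand[gene_index[g], area_index[area]] = eff
        truth_rows.append(
            {"gene_id": g, "area": area, "log2fc": eff, "kind": "handedness_linked"}
        )
    truth = pd.DataFrame(truth_rows, columns=["gene_id", "area", "log2fc", "kind"])

    missing = set(tuple(m) for m in spec.missing)
    sample_ids, meta_rows, cols = [], [], []
    log_base = np.log(spec.baseline_mean) + gene_eff
    ln2 = np.log(2.0)
    for di, donor in enumerate(donors):
        hand_sign = 1.0 if covs.loc[donor, "handedness"] == "R" else 0.0
        for area in spec.areas:
            aj = area_index[area]
            for hemi in ("L", "R"):
                if (donor, hemi, area) in missing:
                    continue
                log_mu = log_base + donor_eff[di]
                if hemi == "R":
                    log_mu = log_mu + ln2 * (lat[:, aj] + hand_sign * hand[:, aj])
                lib_mult = np.exp(rng.normal(0.0, spec.libsize_sd))
                mu = np.exp(log_mu) * lib_mult
                cols.append(_nb_draw(rng, mu, gene_disp))
                sid = f"{donor}_{area}_{hemi}"
                sample_ids.append(sid)
                meta_rows.append(
                    {
                        "sample_id": sid,
                        "donor": donor,
                        "hemisphere": hemi,
                        "area": area,
                        "sex": covs.loc[donor, "sex"],
                        "age": covs.loc[donor, "age"],
                        "handedness": covs.loc[donor, "handedness"],
                        "family_history": covs.loc[donor, "family_history"],
                        "language_disorder": covs.loc[donor, "language_disorder"],
                    }
                )
    counts = np.column_stack(cols).astype(np.int64)
    meta = pd.DataFrame(meta_rows, columns=META_COLUMNS)
    return CountMatrix(genes, sample_ids, counts), meta, truth


# ---------------------------------------------------------------------------
# haplotype panels, LD tables and toy variant resources
# ---------------------------------------------------------------------------


@dataclass
class VariantSimSpec:
    """Design of a toy haplotype panel + GWAS/eQTL/enhancer resource set.

    ``ld_blocks`` is a list of (n_loci, (r2_lo, r2_hi)): each block's loci are
    generated from a shared latent haplotype so that pairwise r-squared falls
    in the target range (exactly 1 when the target is 1).
    """

    n_snps: int
    n_traits: int = 3
    haplotype_panel_size: int = 1000
    ld_blocks: list = field(default_factory=list)
    egene_fraction: float = 0.3
    se_intervals: int = 5
    te_intervals: int = 5
    chrom: str = "chr17"
    chrom_length: int = 1_000_000
    block_span_bp: int = 50_000
    seed: int = 0

    def validate(self) -> None:
        if self.haplotype_panel_size < 2:
            raise SimSpecError("haplotype_panel_size must be >= 2")
        if self.n_snps < 1:
            raise SimSpecError("n_snps must be >= 1")
        if not 0 <= self.egene_fraction <= 1:
            raise SimSpecError("egene_fraction must be in [0, 1]")
        n_block_loci = sum(b[0] for b in self.ld_blocks)
        if n_block_loci > self.n_snps:
            raise SimSpecError("ld_blocks request more loci than n_snps")
        for _n, (lo, hi) in self.ld_blocks:
            if not (0 <= lo <= hi <= 1):
                raise SimSpecError("ld_blocks r2 range must satisfy 0 <= lo <= hi <= 1")


def simulate_haplotypes(spec: VariantSimSpec) -> tuple[pd.DataFrame, np.ndarray, pd.DataFrame]:
    """Simulate a haplotype panel and its derived LD table.

    Returns (variants, panel, ld_table):

    * variants: rsid, chrom, pos (1-based), ref, alt, maf
    * panel: haplotypes x loci 0/1 matrix (column order = variants order)
    * ld_table: rsid_a, rsid_b, r2 (NaN for monomorphic loci), panel label

    The emitted r2 values are computed from the realized panel with
    :func:`hemivox.variant_integration.compute_r2_from_panel`, so table and
    panel agree exactly by construction.
    """
    from .variant_integration import compute_r2_from_panel

    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n, m = spec.haplotype_panel_size, spec.n_snps
    panel = np.zeros((n, m), dtype=np.int8)

    # block loci first, then independent loci
    locus = 0
    for n_loci, (r2_lo, r2_hi) in spec.ld_blocks:
        target = rng.uniform(r2_lo, r2_hi)
        # per-locus flip probability e with (1-2e)^4 = target pairwise r2
        e = (1.0 - target ** 0.25) / 2.0
        z = rng.integers(0, 2, size=n).astype(np.int8)
        if z.min() == z.max():  # keep the latent polymorphic
            z[0] = 1 - z[0]
        for _ in range(n_loci):
            flips = rng.random(n) < e
            panel[:, locus] = z ^ flips.astype(np.int8)
            locus += 1
    while locus < m:
        maf = rng.uniform(0.1, 0.5)
        panel[:, locus] = (rng.random(n) < maf).astype(np.int8)
        locus += 1

    # positions: block loci clustered within block_span_bp, the rest spread out
    pos = np.sort(rng.choice(np.arange(1, spec.chrom_length + 1), size=m, replace=False))
    bases = np.array(list("ACGT"))
    ref_idx = rng.integers(0, 4, size=m)
    alt_idx = (ref_idx + rng.integers(1, 4, size=m)) % 4
    variants = pd.DataFrame(
        {
            "rsid": [f"rs{i + 1:06d}" for i in range(m)],
            "chrom": spec.chrom,
            "pos": pos,
            "ref": bases[ref_idx],
            "alt": bases[alt_idx],
            "maf": panel.mean(axis=0),
        }
    )

    mono = (variants["maf"] == 0) | (variants["maf"] == 1)
    if mono.any():
        warnings.warn(
            f"{int(mono.sum())} monomorphic locus/loci: r2 undefined, recorded as missing"
        )
    rows = []
    for i in range(m):
        for j in range(i + 1, m):
            if mono.iloc[i] or mono.iloc[j]:
                r2 = np.nan
            else:
                r2 = compute_r2_from_panel(panel[:, i], panel[:, j])
            rows.append((variants["rsid"].iloc[i], variants["rsid"].iloc[j], r2))
    ld = pd.DataFrame(rows, columns=["rsid_a", "rsid_b", "r2"])
    ld["panel"] = "SYN"
    return variants, panel, ld


def simulate_variant_resources(
    spec: VariantSimSpec, variants: pd.DataFrame
) -> dict[str, pd.DataFrame]:
    """Toy GWAS, cis-eQTL and enhancer tables over a simulated variant set.

    Known structure: the first locus of each LD block (or the first
    ``n_traits`` loci) gets a genome-wide-suggestive GWAS p-value; a seeded
    ``egene_fraction`` of variants are cis-eQTLs for synthetic genes in 13
    brain tissues; SE/TE intervals are placed so that some cover variants.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed + 1)
    m = len(variants)

    n_hits = max(1, min(spec.n_traits, m))
    traits = [f"trait{t + 1}" for t in range(spec.n_traits)]
    gwas_p = rng.uniform(1e-4, 0.5, size=m)
    hit_idx = rng.choice(m, size=n_hits, replace=False)
    gwas_p[hit_idx] = rng.uniform(1e-9, 1e-6, size=n_hits)
    gwas = variants[["rsid", "chrom", "pos", "ref", "alt"]].copy()
    gwas["trait"] = [traits[i % len(traits)] for i in range(m)]
    gwas["p"] = gwas_p

    n_eqtl = int(round(spec.egene_fraction * m))
    eqtl_idx = rng.choice(m, size=n_eqtl, replace=False) if n_eqtl else np.array([], int)
    rows = []
    for k, i in enumerate(sorted(eqtl_idx)):
        gene = f"EG{k % max(1, n_eqtl // 2) + 1:03d}"
        for tissue in rng.choice(BRAIN_TISSUES, size=rng.integers(1, 4), replace=False):
            rows.append(
                {
                    "rsid": variants["rsid"].iloc[i],
                    "gene_id": gene,
                    "tissue": tissue,
                    "slope": rng.normal(0, 0.5),
                    "p": rng.uniform(1e-8, 1e-3),
                }
            )
    eqtl = pd.DataFrame(rows, columns=["rsid", "gene_id", "tissue", "slope", "p"])

    def _intervals(n_iv: int, kind: str) -> pd.DataFrame:
        out = []
        for _ in range(n_iv):
            if rng.random() < 0.5 and m > 0:
                center = int(variants["pos"].iloc[rng.integers(0, m)])
            else:
                center = int(rng.integers(1, spec.chrom_length))
            half = int(rng.integers(500, 5000))
            start = max(0, center - half)
            out.append(
                {
                    "chrom": spec.chrom,
                    "start": start,
                    "end": min(spec.chrom_length, center + half),
                    "kind": kind,
                    "tissue": "Cortex",
                }
            )
        return pd.DataFrame(out, columns=["chrom", "start", "end", "kind", "tissue"])

    enhancers = pd.concat(
        [_intervals(spec.se_intervals, "SE"), _intervals(spec.te_intervals, "TE")],
        ignore_index=True,
    )
    return {"gwas": gwas, "eqtl": eqtl, "enhancers": enhancers}


# ---------------------------------------------------------------------------
# synthetic ultrasonic vocalization audio
# ---------------------------------------------------------------------------


@dataclass
class SyllableSpec:
    """One synthetic syllable: onset/duration in seconds, frequencies in Hz.

    ``kind``: "tone" (f_start used), "linear" (chirp f_start -> f_end) or
    "sine_fm" (carrier at the midpoint, deviation half the span, modulation
    rate ``mod_rate_hz``).
    """

    onset: float
    duration: float
    kind: str
    f_start: float
    f_end: float
    amplitude: float = 0.5
    mod_rate_hz: float = 100.0


@dataclass
class UsvSimSpec:
    sample_rate: int = 375_000
    syllables: list[SyllableSpec] = field(default_factory=list)
    noise_floor: float = 0.0
    padding: float = 0.02
    edge_fraction: float = 0.2  # raised-cosine taper fraction per syllable
    seed: int = 0

    def validate(self) -> None:
        nyq = self.sample_rate / 2.0
        last_end = -np.inf
        for s in sorted(self.syllables, key=lambda s: s.onset):
            if s.kind not in ("tone", "linear", "sine_fm"):
                raise SimSpecError(f"unknown syllable kind {s.kind!r}")
            if s.duration <= 0:
                raise SimSpecError("syllable duration must be positive")
            if max(s.f_start, s.f_end) >= nyq:
                raise SimSpecError(
                    f"syllable frequency {max(s.f_start, s.f_end)} Hz >= Nyquist {nyq} Hz"
                )
            if s.onset < last_end:
                raise SimSpecError("syllable onsets overlap")
            last_end = s.onset + s.duration


def _instantaneous_freq(s: SyllableSpec, t: np.ndarray) -> np.ndarray:
    if s.kind == "tone":
        return np.full_like(t, s.f_start)
    if s.kind == "linear":
        return s.f_start + (s.f_end - s.f_start) * t / s.duration
    # sinusoidal FM starting exactly at f_start, oscillating toward f_end
    center = 0.5 * (s.f_start + s.f_end)
    dev = 0.5 * (s.f_end - s.f_start)
    return center - dev * np.cos(2 * np.pi * s.mod_rate_hz * t)


def simulate_usv_audio(spec: UsvSimSpec) -> tuple[np.ndarray, pd.DataFrame]:
    """Synthesize a waveform and its ground-truth segment table.

    Ground truth per syllable: onset, duration, kind, f_start, f_end, f_min,
    f_max, amplitude.  Frequency trajectories are integrated into phase, so
    the spectrogram contour follows the analytic instantaneous frequency.
    """
    from scipy.signal.windows import tukey

    spec.validate()
    rng = np.random.default_rng(spec.seed)
    sr = spec.sample_rate
    total = spec.padding + max((s.onset + s.duration for s in spec.syllables), default=0.0)
    n = int(np.ceil(total * sr)) or 1
    wave = np.zeros(n)

    rows = []
    for s in spec.syllables:
        ns = int(round(s.duration * sr))
        t = np.arange(ns) / sr
        f = _instantaneous_freq(s, t)
        phase = 2 * np.pi * np.cumsum(f) / sr
        env = tukey(ns, spec.edge_fraction)
        start = int(round(s.onset * sr))
        wave[start : start + ns] += s.amplitude * env * np.sin(phase)
        rows.append(
            {
                "onset": s.onset,
                "duration": s.duration,
                "kind": s.kind,
                "f_start": float(f[0]),
                "f_end": float(f[-1]),
                "f_min": float(np.min(f)),
                "f_max": float(np.max(f)),
                "amplitude": s.amplitude,
            }
        )
    if spec.noise_floor > 0:
        wave = wave + rng.normal(0.0, spec.noise_floor, size=n)
    truth = pd.DataFrame(
        rows,
        columns=["onset", "duration", "kind", "f_start", "f_end", "f_min", "f_max", "amplitude"],
    )
    return wave, truth


# ---------------------------------------------------------------------------
# canonical benchmark presets (study conditions shared by tests and scripts)
# ---------------------------------------------------------------------------


def usv_benchmark_spec(seed: int = 0, n_syllables: int = 20, sample_rate: int = 375_000) -> UsvSimSpec:
    """A 20-syllable detection/feature benchmark at high SNR.

    Syllables cycle through tone / gentle linear chirp / sinusoidal FM, last
    18-30 ms, and sit 35-97 kHz.  Chirp slopes are kept below the windowed
    contour-quantization bound bin_width / (2 * hop) (~536 Hz/ms at 375 kHz
    with a 512-point FFT and 50% overlap), so frame-level contour estimates
    stay within one frequency bin of the analytic trajectory.  Separation
    >= 50 ms; amplitude 0.5 over a 0.005 RMS noise floor (~30 dB SNR).
    """
    rng = np.random.default_rng(seed)
    syllables = []
    t = 0.06
    for i in range(n_syllables):
        kind = ("tone", "linear", "sine_fm")[i % 3]
        dur = float(rng.uniform(0.018, 0.030))
        f0 = float(rng.uniform(35_000, 90_000))
        if kind == "tone":
            f1 = f0
        elif kind == "linear":
            f1 = f0 + float(rng.choice([-1, 1])) * float(rng.uniform(4_000, 7_000))
        else:
            # sinusoidal FM instantaneous slope is pi * rate * span; keep it
            # below the same quantization bound as the linear chirps
            f1 = f0 + float(rng.uniform(4_000, 6_000))
        syllables.append(
            SyllableSpec(
                onset=t, duration=dur, kind=kind, f_start=f0, f_end=f1,
                amplitude=0.5, mod_rate_hz=25.0,
            )
        )
        t += dur + float(rng.uniform(0.055, 0.090))
    return UsvSimSpec(
        sample_rate=sample_rate, syllables=syllables, noise_floor=0.005,
        edge_fraction=0.1, seed=seed,
    )


def usv_two_family_contours(seed: int = 0, n_per_family: int = 12, sample_rate: int = 375_000):
    """Audio with two well-separated syllable families (flat 50 kHz tones vs
    40->80 kHz chirps) for clustering benchmarks.  Returns (spec, labels)."""
    rng = np.random.default_rng(seed)
    syllables = []
    labels = []
    t = 0.06
    order = rng.permutation([0] * n_per_family + [1] * n_per_family)
    for fam in order:
        dur = float(rng.uniform(0.02, 0.03))
        if fam == 0:
            syllables.append(
                SyllableSpec(onset=t, duration=dur, kind="tone",
                             f_start=50_000.0, f_end=50_000.0, amplitude=0.5)
            )
        else:
            syllables.append(
                SyllableSpec(onset=t, duration=dur, kind="linear",
                             f_start=40_000.0, f_end=80_000.0, amplitude=0.5)
            )
        labels.append(int(fam))
        t += dur + float(rng.uniform(0.055, 0.08))
    spec = UsvSimSpec(sample_rate=sample_rate, syllables=syllables,
                      noise_floor=0.005, edge_fraction=0.1, seed=seed)
    return spec, labels


def handedness_benchmark_spec(
    seed: int = 0,
    n_genes: int = 150,
    n_linked: int = 50,
    delta_log2: float = 1.0,
    n_right: int = 3,
    n_left: int = 3,
) -> ExpressionSimSpec:
    """Handedness-coupled lateralization cohort for the LODO benchmark.

    ``n_linked`` genes in the two language regions (BA44, BA22) carry a
    +delta right-hemisphere bias in right-handed donors (none in left-handed
    donors); BA4 serves as the motor region.
    """
    donors = [f"D{i + 1}" for i in range(n_right + n_left)]
    handed = ["R"] * n_right + ["L"] * n_left
    rng = np.random.default_rng(seed)
    cov = pd.DataFrame(
        {
            "donor": donors,
            "sex": [("M", "F")[i % 2] for i in range(len(donors))],
            "age": rng.integers(63, 88, size=len(donors)),
            "handedness": handed,
            "family_history": ["no"] * len(donors),
            "language_disorder": ["no"] * len(donors),
        }
    )
    genes = [f"gene{i + 1:05d}" for i in range(n_genes)]
    lang = ["BA44", "BA22"]
    linked = {g: (lang[i % 2], delta_log2) for i, g in enumerate(genes[:n_linked])}
    return ExpressionSimSpec(
        n_genes=n_genes,
        n_donors=len(donors),
        areas=["BA44", "BA22", "BA4"],
        handedness_linked_genes=linked,
        covariates=cov,
        seed=seed,
    )


def dumbbell_benchmark_spec(seed: int = 0, n_genes: int = 1500) -> tuple[ExpressionSimSpec, tuple]:
    """Three-area design with an asymmetric within-hemisphere pair.

    60 genes get a +2 right-hemisphere bias in BA44 and 25 in BA22, so the
    right-hemisphere BA22 vs BA44 contrast carries ~85 significant genes
    while the left is null: the (BA22, BA44) pair should top the dumbbell
    ranking.  Returns (spec, expected top pair).
    """
    genes = [f"gene{i + 1:05d}" for i in range(n_genes)]
    lat = {g: ("BA44", 2.0) for g in genes[:60]}
    lat.update({g: ("BA22", 2.0) for g in genes[60:85]})
    spec = ExpressionSimSpec(
        n_genes=n_genes,
        n_donors=5,
        areas=["BA44", "BA22", "BA4"],
        lateralized_genes=lat,
        seed=seed,
    )
    return spec, ("BA22", "BA44")


def write_wav(path, wave: np.ndarray, sample_rate: int) -> None:
    """Write 16-bit PCM mono WAV (clipped to [-1, 1])."""
    from scipy.io import wavfile

    clipped = np.clip(wave, -1.0, 1.0)
    wavfile.write(path, sample_rate, (clipped * 32767).astype(np.int16))


def read_wav(path) -> tuple[int, np.ndarray]:
    """Read a mono WAV to float in [-1, 1]."""
    from scipy.io import wavfile

    sr, data = wavfile.read(path)
    if data.ndim != 1:
        raise SimSpecError("expected mono WAV")
    if data.dtype == np.int16:
        data = data / 32767.0
    return int(sr), np.asarray(data, dtype=float)
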