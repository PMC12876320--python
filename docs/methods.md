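# Methods

This note documents the statistical models, estimators, and numerical
choices behind `hemivox`, and what the synthetic-data generators do and do
not emulate.

## Donor-paired differential expression

Every contrast is paired within donor: left vs right hemisphere within one
Brodmann area (LR), or area vs area within one hemisphere (WH_L, WH_R).
A contrast is restricted to donors contributing both conditions and needs at
least two such donors. Genes are filtered per contrast (subset total count
>= 10 and nonzero in >= 3 subset samples), and TMM size factors are
estimated within the contrast's sample subset.

The default engine (`moderated_t`) works on log2-CPM
(`log2((count + 0.5) / effective_library * 1e6)`):

1. an unweighted per-gene least-squares fit of
   `intercept + donor blocks + condition (+ admitted covariates)` gives
   residual standard deviations;
2. a mean-variance trend — a binned running median of residual sd against
   mean log-CPM (>= 10 equal-count bins, linear interpolation, linear
   extrapolation beyond the outermost bin centers) — predicts a standard
   deviation at each observation's fitted value; weights are `1 / sd^2`.
   Flat extrapolation was rejected: it under-predicts the variance of the
   lowest-count genes and inflates their statistics;
3. the weighted fit's residual variances are shrunk by empirical Bayes
   toward a common prior: a scaled-F moment fit of (d0, s0^2) on log s^2
   (trigamma inversion by Newton iteration), posterior variance
   `(d0*s0^2 + d*s^2) / (d0 + d)`, t statistic on `d0 + d` df.
   `prior_df=0` recovers the ordinary paired t test exactly.

The alternative engine (`nb_wald`) fits per-gene negative-binomial log-link
GLMs with library-size offsets; gene-wise moment dispersions are shrunk on
the log scale toward a running-median mean-dispersion trend (prior weight 3)
and the condition coefficient is tested by Wald z with no outlier filtering.
It is the fidelity option; the moderated-t engine is the tested default
because the two share all contrast logic and the weighted linear model is
far easier to verify against closed-form oracles.

Donor-level covariates (sex, age, handedness, family history, language
disorder) are admitted only when they vary among the donors used; numeric
covariates are median-imputed and robust-standardized
(`(x - median) / (1.4826 * MAD)`), categorical covariates mode-imputed and
one-hot encoded. In a donor-blocked design every donor-level covariate is
exactly collinear with the donor dummies; by default such aliased columns
are dropped and the reason recorded in the contrast's covariate ledger
(`on_aliased="error"` raises instead, listing the aliased columns).

### Multi-level false discovery control

Benjamini-Hochberg at four levels: within contrast (`q_contrast`), pooled
over all genes x contrasts (`q_global`), pooled within contrast family — all
LR contrasts across areas, WH_L, WH_R — (`q_family`), and pooled within the
functional module shared by a contrast's areas (`q_module`; six modules:
Broca = BA44/BA45, Wernicke = BA22/BA21, Geschwind = BA39/BA40, primary
auditory = BA41/BA42, ventral sensorimotor = BA6/BA4/BA3-1-2, other =
BA9/BA37). WH pairs spanning two modules are labeled `mixed` and receive no
module-level adjustment. BH was chosen for the family level as well; the
choice is exposed rather than hard-coded into downstream summaries.

## Lateralization summaries

Significant-gene counts use `q_contrast < 0.05` by default; count maps are
`log10(n + 1)`. The dumbbell statistic per within-hemisphere area pair is
(n_left, n_right, delta = |n_left - n_right|, J), where J is the Jaccard
distance between the two significant-gene sets; ranking is by delta
descending, then J descending, then pair label. Two empty sets get J = 0
(continuity with the equal-sets case) with a warning. Wilcoxon left-right
tests are paired (signed-rank on per-donor right-minus-left values, zero
differences dropped) by default, matching the donor-paired design; the
rank-sum variant is available. Exact null distributions are used for small
n, the tie-corrected normal approximation otherwise.

## Leave-one-donor-out handedness inference

For each held-out donor and region, the R-vs-L moderated-t statistics fit on
the training donors form a signed weight vector; the held-out donor's
right-minus-left log-CPM differences are projected onto it. The default
projection is cosine-normalized so region scores are scale-free before
averaging into language (BA44, BA45, BA22, BA21, BA39, BA40 by default) and
motor (BA4, BA6, BA3/1/2) indices.

The language index maps to P(right-handed) through Gaussian
class-conditionals with a configurable prior (default 0.9, reflecting
population right-handedness). Calibration scores are computed strictly
out-of-sample: each training donor is scored with weights trained without
both that donor and the fold's held-out donor (nested leave-pair-out), so no
fold's calibration ever touches the held-out donor's data. The default
calibration is the symmetric scale-only mapping
(mu_R, mu_L, sigma) = (+sigma_hat, -sigma_hat, sigma_hat), with sigma_hat
the spread of those nested scores: it is a fold-stable monotone map of the
index and uses no handedness labels. Per-class mean calibration
(`calibration="class_means"`) is available but, with the handful of donors a
postmortem cohort provides, its fold-to-fold class-mean noise can invert
posterior order between donors whose language indices order correctly — in
the package's own benchmark it separates the classes in 42/50 simulations
versus 47/50 for the symmetric mapping.

## Variant integration

Sentinels are GWAS records with p < 1e-5 (strict), deduplicated by rsid
keeping the smallest p. LD expansion keeps proxies with r^2 strictly
greater than 0.8 within a symmetric 500 kb window (both configurable).
r^2 = D^2 / (pA pa pB pb) from haplotype counts; it is undefined (missing)
when a locus is monomorphic. Variant positions are 1-based; BED intervals
and the internal gene model are 0-based half-open (GFF3 converted on read),
so a variant at position p overlaps [start, end) iff p - 1 is inside.

Region annotation precedence is exonic > UTR > intronic > upstream /
downstream (within 2 kb of the TSS/TES, strand respected) > intergenic; a
UTR label requires a UTR feature not covered by a plain exon feature.
Enhancer colocalization flags each variant for super-enhancer and
typical-enhancer overlap and tests the discordant counts with the exact
two-sided McNemar test `min(1, 2 * P(X <= min(b, c)))`, X ~ Binomial(b+c, 1/2).

PWM allele scoring renormalizes a JASPAR frequency matrix with a pseudocount
(default 0.01 per cell, uniform background), scores all motif placements and
strands covering the variant on the reference window, fixes the maximizer,
and reports (score_ref, score_alt, delta) in log2-odds bits; the procedure
is invariant under reverse complement of the window. Spearman correlation
uses midranks; the exact permutation p is enumerated for n <= 9 without
ties, the t approximation otherwise.

## Ultrasonic vocalization pipeline

Spectrograms use a 512-point FFT, 50% overlap, Hann taper, restricted to the
25-110 kHz analysis band (at 375 kHz sampling: ~732 Hz bins, 0.683 ms hop).
Detection marks frames whose in-band power exceeds 1.5x the mean frame
power, merges runs across gaps <= 5 ms, applies the duration rule
(> 5 ms, measured as the span of core frame centers — edge windows overlap a
call only partially) and the spectral-purity rule (> 25%, purity = mean
per-frame peak-bin power fraction). Because the Hann taper under-weights
window edges, accepted runs are then extended while the per-frame peak power
stays above 0.1x the run's median peak, and boundaries are reported as
window extent. On the package's synthetic benchmark this places onsets
within one hop and durations within two hops of truth.

Features follow the contour (per-frame argmax frequency): peak / average /
max / min / start / end / median frequency, delta frequency
(|start - end|), bandwidth (max - min), frequency SD, pause duration to the
previous call and its ratio to the call duration, jitter and shimmer
(relative mean absolute successive change of contour frequency and
amplitude — the names are standard but their formulas vary between tools, so
the definition is fixed here). All features except absolute amplitudes are
invariant to global waveform scaling; jitter and shimmer are ratios and thus
also invariant.

Contours are resampled to 32 points, z-scored per dimension, and clustered
by k-means with seeded repeated initialization (best inertia of 3 runs); k
is chosen by silhouette over 2..min(100, n-1) unless fixed. Identical
contours collapse to a single flagged cluster. Group comparisons are
two-sided Mann-Whitney U on per-animal feature means (exact for combined
n <= 20).

## Synthetic data: what it does and does not emulate

Expression: negative-binomial counts with log-link donor, gene, and
hemisphere-by-area effects; per-gene dispersions are log-normal around the
base value (default 0.1, log-sd 0.3), matching the field's standard count
model of gene-specific dispersions around a trend — a constant dispersion
makes the empirical-Bayes prior degenerate (infinite prior df), which no
real dataset exhibits. Library sizes vary log-normally (sd 0.2) so
normalization is exercised. Defaults mirror the atlas design: 5 donors,
both hemispheres, configurable area panels and missingness masks (the
125-of-130 sample layout is representable). Not emulated: gene-gene
correlation, batch structure, cell-type composition — so passing tests show
estimator correctness under the stated model, not robustness to real-tissue
covariance.

Haplotypes: LD blocks are built by flipping a shared latent haplotype with
per-locus error `e` chosen so pairwise r^2 hits the target
(`(1-2e)^4 = r^2`); the emitted LD table is recomputed from the realized
panel, so table and panel agree exactly. Monomorphic loci yield missing r^2
with a warning.

Audio: tones, linear chirps, and sinusoidal FM (a raised-cosine sweep
starting exactly at f_start) with Tukey amplitude envelopes and additive
Gaussian noise; ground truth is analytic. The detection/feature benchmark
(20 syllables, ~30 dB SNR, >= 50 ms separation) keeps chirp slopes below the
contour quantization bound `bin_width / (2 * hop)` (~536 Hz/ms) — the
frame-level contour of a steeper sweep cannot track its endpoints to within
one bin, so accuracy claims are made where the measurement is well-posed.
Not emulated: reverberation, overlapping callers, amplitude modulation
beyond the envelope.

## Problem sizes used by the test suite and acceptance script

Null error control: 2,000 genes x 5 donors x 20 simulations. Effect
recovery: 120 genes with a +2 log2 right bias among 1,500. Dumbbell
ranking: 50 simulations of a 3-area, 800-gene design with 60/25 lateralized
genes creating one known asymmetric pair. Handedness: 50 simulations of a
6-donor (3 right-, 3 left-handed) cohort, 50 handedness-linked genes at
+1 log2 across two language regions among 150 genes. USV: the 20-syllable
benchmark plus a 24-syllable two-family clustering set. These sizes were
chosen to give stable Monte-Carlo estimates on a single CPU in minutes.

## Known limitations

- The `nb_wald` engine's moment/trend dispersion shrinkage is simpler than a
  full maximum-a-posteriori dispersion fit; it is intended for small
  fidelity checks, not large atlases.
- The intra-donor-correlation (generalized least squares) option for the
  LODO design is approximated by the fixed donor block; consensus
  correlation weighting is not implemented.
- Posterior handedness probabilities are monotone, well-ordered scores;
  their absolute calibration depends on priors and class-conditional
  assumptions the underlying study cannot verify.
- The USV detector assumes a single caller and a stationary noise floor;
  the intensity threshold is relative to mean frame power and will shift
  with duty cycle.
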