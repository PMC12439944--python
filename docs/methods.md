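# Methods

This note documents the models implemented in `lysorna`, the choices made
where the design was genuinely open, and what the synthetic-data generator
does and does not emulate.

## Counting and normalization

**Fractional multimap counting** (`quantify.fractional_count`) operates on
tidy read-assignment tables (read × candidate feature), not BAM files:
alignment is out of scope, and the table dialect keeps the package
dependency-light and testable. A read mapping to *n* loci contributes 1/*n*
to each, so per-sample column sums equal read totals exactly; accumulation
is plain float64 (error < 10⁻¹² at the table sizes this package targets,
against a contract tolerance of 10⁻⁹). References are assumed to have been
searched sequentially (rRNA → tRNA → mitochondrial → abundant ncRNA → whole
transcriptome); merging per-tier matrices keeps the first instance of each
gene id, warning when later tiers disagree on a length. Reads are assumed
already strand-filtered upstream. RPK normalization divides by length in
kilobases and is skippable — the pulse-chase arm does not length-normalize.

**Spike-in normalization** (`spikein`). Spikes must show ≥ `min_reads`
(default 10) reads in at least `ceil(min_sample_fraction × n_samples)`
samples (default 0.75, generalizing an 18-of-24 design rule). The
per-sample standard curve is an ordinary least-squares regression of spike
signal on known concentration *with* an intercept — the intercept absorbs
additive background and is discarded; only the slope β_s is used. The
regression is computed on whatever scale the spike table supplies; when RPK
mode is on for genes, supply spike RPKs for strict scale consistency (the
enrichment ratio is invariant to this choice because gene length cancels).
Normalized value = (value / β_s) × f_s where f_s is the per-sample capture
factor, an experimental input (e.g. LAMP2 immunoblot intensities). No
pseudocounts anywhere; zeros propagate.

**Enrichment** (`enrichment`). E = mean(normalized lyso replicates) /
mean(normalized whole-cell replicates); the mean is taken *before* the
ratio. Genes with zero whole-cell mean get E = NaN rather than a
pseudocount: a pseudocount would fabricate enrichment for lyso-only
detections. The dependence ratio D = E_KO / E_control is NaN whenever
either term is undefined. Summaries report n, median and quartiles by RNA
class, protein-localization class, or TOPscore bin; TOPscore bins are
right-closed with a default boundary at 3.0 so "score > 3" forms the top
bin. tRNA rows with identical sequences are collapsed by summation before
tRNA-level analysis, keeping the lexicographically first id and the member
list. Spearman correlation is computed as Pearson on average ranks
(mean-rank ties); constant vectors are flagged NaN rather than guessed.

## Decay model

Per gene, genotype and replicate, with y the log2 of the nLuc- and
t0-normalized signal at chase time x (hours):

* `background_mode="log_offset"` (default, the protocol as printed):
  y = log2(C e^(−kx)) + z.
* `background_mode="linear_plateau"`: y = log2(C e^(−kx) + z), the
  physically motivated form in which the mock-IP background is a
  linear-scale plateau the decaying signal sinks into.

The two coincide as z → 0 and differ materially only for fast-decaying
genes observed past the point where signal reaches background. The
log-offset form cannot represent a plateau, so with a plateau-generating
process and z ≈ 10⁻⁴, genes with t½ ≲ 3 h are systematically
underestimated under it; recovery analyses here therefore use
`linear_plateau`, and the default remains the literal printed form.

**Background term.** z = max(max of 4 mock-IP values, 5·10⁻⁶) / (spike-
normalized reads at t = 0). The protocol wording is ambiguous about what
the division applies to; the alternative reading
z = max(mock max, 5·10⁻⁶ / t0 reads) is available as
`z_mode="floor_quotient"`. The scale of the mock values (nLuc- vs
spike-normalized) is likewise not pinned down; the generator emits them on
the spike-normalized scale consistent with its `t0_reads`.

**Fitting.** Bounded least squares (`scipy.optimize.least_squares`, TRF,
analytic Jacobian, ftol = xtol = gtol = 10⁻¹⁰, deterministic — no random
restarts). C, k ∈ [0, ∞) with starting values C₀ = 2^max(y), k₀ = 1; C's
lower bound is implemented as 10⁻¹² so log2(C) stays finite. For
Torin1-treated series C is fixed to the untreated fit's C of the same
replicate (the initial labeled amount predates treatment divergence); the
supplied C is returned unchanged, bit-exactly. Standard errors come from
the asymptotic covariance s²(JᵀJ)⁻¹ with residual df = n − n_free, and
two-sided Wald t p-values from them; the original analysis inherits a
specific tool's defaults, which are not published, so this standard choice
is ours. A k estimate at the zero boundary gets p_k = 1 — a boundary
estimate is not evidence of decay. Fits are retained when p_k < 0.05 and
(C fixed or p_C < 0.05) and the optimizer converged. t½ = ln(2)/k capped
at 50 h (k = 0 maps to the cap); S = C·k; replicate half-lives are averaged
arithmetically after filtering, per replicate first, never pooled.

**Stability.** A = (t½_WT,Torin1 / t½_WT) / (t½_KO,Torin1 / t½_KO),
defined only when all four half-lives exist. Swapping the genotype labels
maps A to 1/A (exact up to one float division rounding).

## The synthetic-data generator

The generator emulates both experimental designs with known per-gene truth
so every stage is testable by parameter recovery. Defaults are the
emulated study conditions; sizes are scaled to desk use.

* **Classes.** Ten RNA classes (bulk/TOP/membrane/secretory mRNA, tRNA,
  Y RNA, SRP RNA, vault RNA, snRNA, mito RNA) allocated by largest-
  remainder apportionment (ties broken by class name). True enrichment
  E = baseline × class multiplier × lognormal jitter; multipliers span
  0.2–30 (mito depleted, SRP RNA most enriched) and the jitter is 1.0 log2
  units, matching the decade-wide within-class spreads such data show.
  tRNA enrichment is mildly coupled to the Kyte–Doolittle hydropathicity
  of the carried amino acid. TOPscores are > 3 for the TOP class and < 3
  for other mRNAs.
* **Fraction counts.** Whole-cell expected counts are abundance ×
  `wc_mean_counts` (default 100; abundance lognormal, 1.0 log2 sd); LysoIP
  expected counts scale additionally with E and are divided by the
  sample's capture factor, so the downstream × f_s correction inverts the
  distortion exactly. Gene counts are negative binomial
  (var = μ + 0.1 μ² by default; Poisson at dispersion 0; exact means with
  noise off). Equal spike amounts are added to every sample — reads linear
  in the 24-point concentration ladder, scaled so spikes are ~0.1% of a
  whole-cell library (inside the 0.01–0.2% design window) — and spike
  counts are Poisson only, since spikes are a shared technical pool with no
  biological replicate variability. The constant spike amount is what makes
  noiseless enrichment recovery exact rather than merely rank-preserving.
* **Pulse chase.** Timepoints {0, 1, 2, 4, 8, 28} h, two replicates, true
  half-lives log-uniform in [0.5, 30] h, signal C e^(−kt) + background
  plateau (10⁻⁴ of the t0 signal), multiplicative lognormal noise (0.1
  log2 sd) on genes and on per-sample depth, an nLuc spike row per sample,
  and four mock-IP samples at the plateau level. Torin1 multiplies k by a
  per-genotype factor (default: ×2 in WT, ×1 in ATG7-KO — autophagy-
  dependent destabilization). Within a genotype/replicate the t = 0 sample
  is shared between the untreated and Torin1 arms, because treatment
  begins at the chase start; this shared initial sample is what makes
  fixing the Torin1 C to the untreated estimate beneficial rather than
  harmful.
* **Not emulated:** read-level artifacts (FASTQ, alignment, UMIs, GC
  bias), mitochondrial contamination of WT lysosomes, transcription-rate
  changes during the chase, multi-exponential decay (e.g. processed
  ncRNA species), and library-size/dispersion values from the real data,
  which were not published — defaults here are chosen for testability.
  Passing recovery tests therefore demonstrates correctness of the
  estimators under the stated noise model, not performance on real
  libraries.

## Problem sizes used in the automated checks

Recovery checks run at 2,000 genes (enrichment; NB dispersion 0.1,
whole-cell mean 100) and 500 genes × 2 replicates (decay; log2 noise 0.1),
with 200–250 genes for the shared-C and stability calibrations; the
grid-search cross-check uses a 400 × 400 log-spaced (C, k) grid on 20
genes. Smaller fixtures (60–900 genes) back the unit tests. Small synthetic
libraries carry proportionally few spike reads, so fixtures below ~1,000
genes relax the spike coverage filter to `min_reads=1`; the default of 10
is meant for realistic sequencing depth.

## Known limitations

* The Wald p-values are asymptotic and anti-conservative at 6 timepoints;
  they reproduce the original filtering behavior rather than offering
  exact inference.
* With `log_offset` (the literal default) the background term is a pure
  log-space shift; do not use it to estimate half-lives of transcripts
  that plateau within the observation window.
* Capture factors are inputs; the package does not estimate them, and the
  spike cross-sample identity only holds when they are equal.
* The half-life cap (50 h) makes the estimator biased for very stable
  RNAs by construction; capped values should be treated as "≥ cap".
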