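# Methods

This note documents the models, conventions and numerical choices behind
`truthbench`, and what the synthetic testbed does and does not show about
real data.

## Conventions shared by all modules

Expression matrices are genes × samples with a declared scale tag
(`counts`, `fpkm`, `log2fpkm`, `cpm`, `tpm`, `normalized`). Log transforms
use log2(FPKM + 0.01); the 0.01 pseudo-count keeps unexpressed genes finite
at log2(0.01) ≈ −6.64. Relative expression is computed within each
laboratory: per gene, the mean over the lab's own D6 (or MAQC B) replicates
is subtracted from every sample of that lab, so the reference mean is 0 by
construction and any per-gene, per-lab additive offset cancels. Comparisons
are named `<numerator>/<denominator>` with D6 the denominator for the
quartet and mixture samples and MAQC B for the MAQC pair.

## PCA-based SNR

Genes are centered and scaled to unit variance across the included samples
(zero-variance genes dropped with a warning), PCA is taken over samples, and
each sample is placed at (f1·PC1, f2·PC2) where f1, f2 are the
explained-variance fractions. Signal is the mean squared Euclidean distance
over all unordered group-centroid pairs; Noise is the mean squared distance
of replicates to their group centroid (a pairwise-replicate alternative is
available via `noise_mode="pairwise"`); the score is 10·log10(Signal/Noise)
in decibels. Zero Noise (replicates exactly at their centroids, within
1e-12 of the Signal magnitude) returns +∞ rather than a cap. Gene inclusion
for SNR uses ≥ 1 read in any included sample (`min_reads` exposed).

Two properties of this formula worth knowing:

- It is invariant to gene order and per-gene affine rescaling (by
  construction of the unit-variance scaling).
- For groups drawn from a single distribution the score is *not* 0 dB:
  centroids of k replicates carry sampling variance ∝ 1/k, so the null
  score sits below 0 dB and decreases with k. Tests assert oracle equality
  and an upper bound rather than "≈ 0".

The leave-one-out rule recomputes the SNR with each sample excluded
(skipping samples whose group would fall below two replicates) and flags a
sample when SNR17 − SNR18 > 6 dB.

## Titration built-in truth

T1 and T2 mix M8 and D6 total RNA at 3:1 and 1:3. Differing mRNA fractions
of the parents are corrected by a shift coefficient z through
k1 = z/(z+3) and k2 = 3z/(3z+1); the calibrated defaults are z = 0.974 (T1)
and z = 0.949 (T2). Two coefficient conventions are implemented and the
difference is deliberate:

- `as_printed` (default): T1 = k2·M8 + k1·D6 and T2 = k1·M8 + k2·D6, i.e.
  k1 and k2 are used directly as the two weights. Their sum is 0.990 at
  z = 0.974 — mass is not conserved off z = 1.
- `mass_balance`: the minor weight is replaced by the exact complement
  (1/(3z+1) for T1, 3/(z+3) for T2), conserving mass for every z and
  admitting a closed-form per-gene z estimate
  (T1: z = (E_mix − E_D6)/(3(E_M8 − E_mix))).

The modes coincide exactly at z = 1. Neither is asserted as the "right"
reading; the default follows the printed formulas.

Per-gene z estimation divides by E_M8 − E_mix, which for a 3:1 mixture
cancels about three quarters of the magnitude: measurement noise of 10% per
abundance translates into per-gene z errors well above 0.2, with heavy
tails near E_M8 ≈ E_mix (such genes are skipped). Per-gene averaging is
therefore only appropriate for assay-grade measurements (few-percent CV,
e.g. RT-qPCR) on strongly differential genes. For sequencing-grade noise
the package estimates z globally by a robust fit of the titration curve
log2 E_mix/D6 = log2(w_d6 + w_m8·2^x) over all genes: Tukey-biweight IRLS
(tuning constant 4.685, MAD scale, ≤ 50 iterations, |Δz| < 1e-8), with the
inner 1-D weighted problem solved by bounded scalar minimization on
z ∈ (1e-3, 1e3). Reported RMSE compares observations to the expected curve
at the *configured* z, not the fitted one.

The fold-change filter sweep ranks genes by |observed log2 M8/D6| and
recomputes the RMSE at decreasing retention. Whether tightening retention
lowers the RMSE depends on who occupies the high-|FC| tail: when true DEGs
are well measured and dominate it, RMSE falls; when the tail is
noise-inflated low-expression ratios (the failure mode of poor datasets),
RMSE rises. Both regimes occur in the test suite; the package reports the
table and does not assume a direction.

## Normalization

CPM, FPKM and TPM follow their defining formulas (TPM divides by length
first, so columns sum to 1e6 exactly). The between-sample methods return
size factors with the single orientation `normalized = count / factor`:

- **TMM**: reference sample = the one whose upper quartile of nonzero
  counts is closest to the mean upper quartile; M and A computed on
  count fractions over genes nonzero in both; two-sided rank trimming of
  30% on M and 5% on A; delta-method precision weights; factor =
  library size × 2^(weighted mean M); factors rescaled to geometric mean 1.
  Trim constants and weighting follow the canonical implementation's
  defaults (the comparison study ran that implementation); the test suite
  cross-checks against edgeR via Rscript.
- **Upper quartile**: 75th percentile after removing all-zero genes,
  rescaled to geometric mean 1.
- **Median-of-ratios**: per sample, median over genes nonzero in every
  sample of count/geometric mean; the median is taken on the log scale so
  even-count ties average geometrically, matching DESeq exactly (verified
  against DESeq2 in the tests). No rescaling, matching that tool.

## DEG evaluation

The truth-labeling rule mirrors RT-qPCR practice: Student t-test p < 0.05
AND linear fold change ≥ 2 or ≤ 0.5; direction from the sign. The
confusion classification penalizes non-reporting: every assessable truth
gene lands in exactly one cell; truth DEGs reported with matching direction
are TP; reported not_de, reported with the opposite sign, or absent are FN
(absences also tallied as unreported; opposite signs tallied as direction
errors, with a config switch to score them FP instead — the default
preserves cell-total conservation). MCC uses the standard
zero-denominator → 0 convention. The ranking AUC scores −log10(p) with
mid-ranked ties; unreported genes take the worst rank by default.

The internal caller is plumbing, not a reimplementation of edgeR/DESeq2:
Welch t on log2 values plus a fold-change cut. Two defaults make it behave
like real tools where that matters: per-sample median recentering (the
log-space analogue of median-of-ratios size factors), because asymmetric
DE shifts depth-normalized composition and would otherwise fold-change
every non-DE gene; and, inside the filter sweep, Benjamini–Hochberg
correction, because without FDR control removing genes can never increase
the number of discoveries and the threshold effect the sweep studies cannot
exist. The sweep computes max/median/sum of counts or CPM over the
comparison's replicates, removes the lowest `t` percent of genes
(t ∈ [0, 70]), re-calls, and scores TPR/precision with filtered truth DEGs
counted as FN.

## PVCA

(i) PCA over samples (genes unit-scaled); retain the smallest leading set
of components with cumulative explained variance ≥ 0.6 (configurable).
(ii) Per component, fit y = μ + Σ u_k + e with independent random effects
per factor by EM-REML: the textbook conditional-expectation updates with a
projection matrix for the fixed intercept, safeguarded Aitken extrapolation
every three iterates to collapse EM's geometric tail, an absorbing zero
boundary at 1e-8 of the response variance (plain EM approaches zero
sublinearly), tolerance 1e-9, ≤ 2000 iterations. On balanced one-way
designs this reproduces the ANOVA closed form ((MSB−MSW)/n, truncated at 0)
to < 1e-6, and it agrees with statsmodels MixedLM variance components on
crossed designs (test-verified). (iii) Components are averaged across
retained components weighted by raw eigenvalues. (iv) Normalized into
proportions including the residual.

Sample-type membership enters as one `sample_group` term so biological and
technical proportions can be compared. Numeric factors are quartile-binned
(configurable). Factors inducing *identical* sample partitions are reported
as aliased with a warning — their variance split is arbitrary — rather than
silently divided; pairwise interactions are opt-in and restricted to
replicated combination levels.

## Synthetic panel generator

Per-gene baseline log2 abundance ~ N(1, 2.5²) (long-tailed on the linear
scale); gene lengths log-normal around 1.5 kb. Sample-type effects are
sparse planted log2 shifts recorded verbatim as truth: quartet types use
fraction 0.05 with sd 0.8 (the twin sample scaled by 0.4, emulating its
near-identity to the control without pedigree modeling), the MAQC pair
fraction 0.5 with sd 3.0. The MAQC magnitudes are calibrated so the planted
biological variance (~4.7 log2²) clearly exceeds the summed technical
factor variance (~1.6) — the defining property of that sample pair, whose
real counterparts differ in over half the transcriptome with large fold
changes; the first-draft values (0.35/2.5) left the two sources
statistically indistinguishable at panel size. Mixture abundances follow
the titration weights at the true z (default 0.974/0.949, `as_printed`).
Technical structure: each laboratory draws one level per protocol factor
(enrichment sd 1.0, strandedness 0.6, kit 0.4 — ordering chosen to mirror
enrichment being the dominant experimental source), one batch vector
(sd 0.3), and per-library replicate noise (sd 0.2), all gene-specific log2
effects. Counts are negative binomial (dispersion 0.05, var = μ + φμ²)
around expected fragment shares (FPKM × length) at library sizes 2–8 M;
dispersion 0 short-circuits to deterministic expected counts so noise-free
limits are exact. FPKM is then derived from the realized counts. Spike-ins
append 92 rows: Mix 1 drives M8, Mix 2 drives D6, mixtures get the
z-corrected blend, spike-in-free types get zero plus an optional
contamination rate. The concentration ladder spans 20 doublings, 23
controls per subgroup, since only the subgroup ratios and a wide dynamic
range are constrained by the design.

What the generator does not emulate: GC/length bias curves, isoform
structure, read-level artifacts, expression-correlated protocol effects,
or heavy-tailed outlier laboratories. Passing tests therefore demonstrate
the correctness and calibration of the assessment machinery under the
declared noise model, not the field performance of any laboratory.

## Experiment sizes

The packaged experiments (`truthbench.experiments`) run the framework at
desk scale: z recovery with 2000 genes × 100 runs, outlier detection with
300 genes × 18 libraries × 100 runs, SNR and PVCA contrasts on 1200–1500
genes across 3–8 laboratories, crossed-factor REML ordering at 8×8×2 × 100
runs, and the filter sweep on 3000 genes. These sizes give stable Monte
Carlo rates (binomial SE ≲ 2% at the asserted thresholds) while keeping the
full suite in well under half an hour on one core.

## Known limitations

- The multi-laboratory pooled analyses re-center per laboratory; a global
  re-centering mode is not provided.
- The printed-coefficient titration mode does not conserve mass off z = 1;
  this is faithful to the formulas but means its fitted z is not exactly
  comparable to the mass-balance closed form away from z = 1.
- EM-REML assumes independent random effects with homogeneous residuals;
  no covariance structures, fixed-effect covariates, or degrees-of-freedom
  corrections.
- QC thresholds are evaluated strictly as printed; a relaxed boundary mode
  exists but reproduces no published convention.
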