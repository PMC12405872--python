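# Methods

This note documents the statistical model behind `panelgwas`, the defaults
and numerical choices, what the synthetic-data generator does and does not
emulate, and known limitations.

## Study design being modeled

The package targets quantitative traits measured on panels of fully inbred,
fully sequenced lines (DGRP-style). Each line is phenotyped on replicate
individuals (here: dopaminergic neuron counts summed over the PPM1/2, PPM3
and PPL1 brain clusters, 7–36 brains per line), and lines are processed in
experimental batches (15 batches of 8–14 lines). Two internal control
strains — one trait-sensitive, one trait-resistant — are re-measured in most
batches (11 of 15) and anchor the batch correction. Because lines are
homozygous, the between-line variance captures the total genetic variance
and the line mean is the natural unit for association.

## Batch correction

For batch *b*, the residual is
r_b = (combined control mean in *b*) − (combined control mean overall),
and every count in *b* is shifted by −r_b. Two definitions of "combined
mean" are implemented:

* **equal line weight** (default): the unweighted mean of the per-control
  per-batch means. Robust to unequal brain numbers between the two controls
  in a batch.
* **pooled** (`pooled=True`): all control brains in the batch pooled.

The overall reference is the unweighted mean over control-bearing batches of
the per-batch combined means, which makes the residuals sum to exactly zero
over those batches and leaves the corrected combined control mean identical
(to ~1e-15) in every corrected batch. Batches without controls keep their
raw values (r_b = 0) with a logged warning. Correction subtracts the same
constant from every line in a batch, so within-batch line contrasts are
preserved exactly in exact arithmetic (one floating-point rounding step in
practice — tests assert at 1e-12).

## Broad-sense heritability

Within each batch, a one-way random-effects ANOVA on **raw** (uncorrected)
per-individual counts gives method-of-moments components:
MS_between and MS_within from the usual table,
n₀ = (N − Σnᵢ²/N)/(k − 1) for unequal replicate numbers nᵢ,
σ²_L = max(0, (MS_between − MS_within)/n₀), σ²_E = MS_within, and
H² = σ²_L/(σ²_L + σ²_E) (0 when both components vanish). The overall
estimate is the unweighted mean of the per-batch H² values. Control lines
measured in a batch are included in that batch's ANOVA by default
(`include_controls=False` excludes them). REML-based H² and confidence
intervals are deliberately out of scope; the moment estimator is what the
emulated analysis uses.

The ratio of truncated moment estimators is slightly biased at batch sizes
of ~12 lines: at a true per-individual H² of 0.85 the replicate mean
estimate is ≈ 0.83 (downward, from the nonlinearity of the ratio plus the
extra ~1/12 count-rounding variance entering σ²_E), and at 0.2 it is ≈ 0.19.
Both are well within the ±0.05 recovery band the tests enforce.

## Genomic relationship matrix

Calls are coded 0/1 (reference/alternate homozygote). With p_m the
alternate-allele frequency of variant m among non-missing calls,
A_jk = (1/M) Σ_m (x_jm − p_m)(x_km − p_m) / (p_m(1 − p_m)).
Missing calls are mean-imputed for the GRM only; monomorphic variants are
excluded. Under this standardization the diagonal averages ≈ 1 and the
matrix is PSD up to numerical noise (eigenvalues are clipped at 0). A
per-variant weight vector makes duplicated variants equivalent to doubled
weights.

## Mixed-model association

On line means the null model is y = X₀β + u + e, u ~ N(0, σ²_g A),
e ~ N(0, σ²_e I); X₀ is an intercept plus, when known for every line,
Wolbachia infection and the five major inversion karyotypes as fixed
effects (constant columns are dropped). The restricted likelihood is
profiled over δ = σ²_e/σ²_g on the eigenbasis of A: one eigendecomposition
serves every evaluation, δ is scanned on a 61-point log grid spanning
10⁻⁵–10⁵ and refined by bounded scalar minimization (tolerance 1e-10 in
log₁₀δ, i.e. far below 1e-8 in δ). A flat profile — A numerically
indistinguishable from a multiple of the identity, or an optimum pinned at
the upper grid edge — resolves to σ²_g = 0 with a warning.

Each variant is tested as a fixed effect with the variance-component
*ratio* held at the null fit and the overall scale re-estimated from the
weighted residual sum of squares (n − rank(X) denominator): a Wald *t* with
n − rank(X) degrees of freedom. This choice makes the test collapse exactly
onto the ordinary-least-squares *t*-test when σ²_g = 0 and keeps type-I
error calibrated (verified by permutation at α = 0.05, 0.01, 10⁻³).
Lines with a missing call are dropped pairwise per variant; complete
variants go through a vectorized rotation path that is identical (≤ 1e-8,
typically 1e-14) to a dense GLS solve, and variants with missing calls use
a rank-aware dense solve (SVD least squares after Cholesky whitening) that
skips variants rendered monomorphic or collinear by the deletion. Perfect
fits report the smallest positive float rather than p = 0. A
likelihood-ratio mode (`test="lrt"`, at fixed weights) and an exact
per-variant REML re-fit (`refit=True`, for small panels) sit behind flags.

Genomic inflation is λ = median(χ²₁(p)) / qchisq(0.5, 1); Q-Q coordinates
pair the rank-i expected quantile −log₁₀((i − 0.5)/n) with sorted observed
p-values.

## Post-scan interpretation

* **LD loci**: squared Pearson correlation of call vectors over
  pairwise-complete lines (pairs with < 3 complete lines are treated as
  below threshold); loci are connected components at r² ≥ 0.5 — a
  deterministic, order-independent partition.
* **Gene assignment**: a SNP belongs to every gene whose transcription
  boundaries ± 1 kb (inclusive) contain it on the same chromosome; strand
  ignored; no nearest-gene fallback — unassigned SNPs are intergenic.
* **Threshold report**: strict inequality at each p cutoff; gene counts are
  distinct genes among assigned hits; intergenic hits counted separately.
* **Enrichment**: one-sided hypergeometric upper tail (equivalently
  Fisher's exact test, cross-checked against an independent implementation
  in the tests); expected = nK/N with n the number of *mapped* input genes;
  fold·expected = observed holds exactly; BH FDR across tested pathways.
  The pathway database itself is an input (GMT), never bundled.

## Synthetic panels

The generator is the package's stand-in for study data and defines the
conditions the tests run under:

* **Genotypes**: biallelic homozygous calls in blocks of `ld_block_len`
  (default 10) consecutive markers; each non-seed variant copies its
  block's seed call per line with probability `ld_copy_prob` (default 0.7),
  else draws Bernoulli(MAF) independently; MAF ~ Uniform(0.05, 0.5);
  2% missing calls at random. This yields tunable within-block r² without
  coalescent machinery — there is deliberately no recombination map,
  selection, or realistic allele-frequency spectrum.
* **Phenotypes**: counts are round(mean + g_line + batch + residual)
  truncated at 0 with mean 26 neurons, batch offsets N(0, 1.5²) and
  per-brain residual SD 2.0 (a free parameter — per-line dispersion is not
  a published constant). Counts are modeled as additive Gaussians rather
  than sums of per-neuron survival Bernoullis because the downstream
  estimators treat the total as an additive quantitative trait.
* **Genetics**: `n_causal` (default 10) common variants get Normal effects;
  a polygenic per-line top-up scales total genetic variance to
  target_H2/(1 − target_H2)·σ²_e (target 0.85). Drawn effects are shrunk if
  they alone would exceed the target share, so the realized heritability
  hits the dial; *explicitly planted* effects (power analyses) are never
  rescaled and the realized H² is recorded in `SimTruth`. Control lines
  carry one genetic value across all their batches.
* **Design**: 186 lines, 15 batches (test lines split as evenly as the
  8–14 range allows), two controls present in 11 batches (a contiguous run
  of batches, the 2nd through 5th, lacks them, mirroring the emulated
  study); 7–36 brains per line-batch; Wolbachia ~ Bernoulli(0.53),
  inversion frequencies 0.15/0.10/0.10/0.10/0.05; per-line survival
  ~ Beta(4.5, 0.1875) (mean 0.96, range matching a 52–100% spread).

Passing parameter-recovery and power tests on these panels demonstrates
estimator correctness under the generator's additive, block-LD world; it
does not establish robustness to features real panels have and the
generator lacks (rare structural variation, segregating inversions in LD
with causal sites, non-Gaussian count dispersion, batch-by-line
interactions).

## Problem sizes used in the shipped checks

Simulation-based checks run at sizes chosen to make Monte-Carlo error small
relative to their tolerance bands while staying desk-scale: 50 random
instances (8–20 lines) for the dense-GLS oracle, 10,000 independent markers
on 150 lines for permutation calibration, 200 replicate panels per
heritability target, and 100 seeded 120-line/1,500-marker runs for the
planted-variant power sweep. The acceptance script reports the same
quantities at 40–50 replicates.

## Known limitations

* Exact reproduction of portal-computed association p-values is not
  guaranteed: the portal's covariate pre-adjustment and its kinship
  normalization are not published, so real-data comparisons are
  tolerance-based. Joint fixed-effect covariates are the default here.
* The per-SNP test reuses the null variance ratio (the standard
  population-parameters-previously-determined approximation); the exact
  re-fit exists but is quadratic-cost and intended for small panels.
* No VCF ingestion (DGRP freeze 2 ships as tgeno), no liftover, no GO-graph
  propagation, no epistasis or gene-environment interaction terms, and no
  ortholog mapping — orthologs, like pathway membership, are annotation
  inputs.
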