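# Methods

## The model

`methtraj` analyses longitudinal Infinium-array DNA methylation. For CpG
*j* and individual *i* with observations at ages *t*, the trajectory is an
ordinary least-squares line per (CpG, individual) pair,

    beta_ij(age) = gamma_ij + alpha_ij * (age - age_ref),

fitted only when the pair has at least `min_points = 3` observations at
distinct ages. The per-CpG rate of change is the mean slope
mu_j = (1/N) * sum_i alpha_ij, tested against zero with a two-sided
one-sample t-test on N-1 degrees of freedom and Bonferroni-corrected
across the CpGs tested in the run. Fitting each individual separately
makes no pooling assumption; the standard pooled alternative — a
random-intercept linear mixed model

    beta_ij = alpha_j * age_i + gamma_i + eps_ij,   gamma_i ~ N(g, tau^2)

— is fitted per CpG by REML as a cross-check. On these data the two
estimators agree essentially perfectly (Pearson r > 0.999 on the synthetic
study design), which is why the per-individual fits, whose slopes are
needed downstream anyway, are the primary estimator.

### Fast profiled REML

Fitting a general-purpose mixed-model routine per CpG is two to three
orders of magnitude slower than necessary for array-scale data. For the
random-intercept model the covariance of individual *i* is
V_i = sigma_e^2 (I + lambda 11') with lambda = tau^2 / sigma_e^2, and
Sherman-Morrison gives V_i^{-1} in closed form. All GLS quantities then
reduce to per-individual sufficient statistics (n, Sx, Sxx, Sy, Syy, Sxy),
so for any lambda the REML criterion of every CpG costs O(1) once those
statistics are aggregated by group size. The implementation profiles out
the fixed effects and sigma_e^2, evaluates the criterion on a coarse
lambda grid (0 plus 56 log-spaced points in [1e-6, 1e5]), and refines each
CpG's optimum by a vectorised golden-section search on log(lambda) to a
bracket below 1e-10 (criterion tolerance ~1e-8). The boundary solution
lambda = 0 is retained whenever it is at least as good as the interior
optimum. Tests verify agreement with statsmodels MixedLM (fixed effects)
and with a dense profile-likelihood grid search (variance components) on
unbalanced 3/4-wave data.

## Cell-composition correction

Betas are residualised per CpG on the five directly measured white-cell
counts (neutrophils, lymphocytes, monocytes, eosinophils, basophils; raw
counts as regressors, with intercept), or on proportions estimated from
the betas by reference-based deconvolution. Deconvolution solves a
nonnegative least-squares projection of each sample onto the reference
profiles and rescales the weights to the simplex; the reference matrix
must be full column rank. Residualisation is a linear projection, hence
idempotent, and the corrected matrix feeds back into trajectory fitting
unchanged.

To quantify how much slope variation blood composition explains, each
cell type's within-sample proportion is regressed on age per individual
(requiring >= 3 count timepoints), and per CpG the individual slopes are
regressed on four of the five cell-type rates — one is dropped because
proportions sum to one; lymphocytes by default, being most collinear with
neutrophils. The per-CpG F-test is Bonferroni-corrected at 0.01, R^2 and
variance-inflation factors are reported, and re-fitting with a different
dropped type leaves fitted values and R^2 unchanged (reparameterisation
invariance, tested).

## Rapid-gain CpGs

The distribution of significant mean slopes shows a bulk near zero and a
shoulder of rapidly gaining CpGs. The class boundary is the left edge of
the first local-minimum bin to the right of the global mode, on a
histogram with fixed 0.0005 beta/year bins anchored at integer multiples
of the bin width (so detection is invariant to padding with negative
slopes). Counts are smoothed with a 3-bin moving average before valley
detection because single-bin noise near the valley is comparable to the
bin-to-bin signal; raw counts are reported. Classification is strict
(`mu_j > threshold`). A unimodal distribution raises an error and the
pipeline accepts a user-supplied threshold instead.

## CpG density and annotation

Coordinates are 0-based half-open everywhere; a manifest position is the
C of a forward-strand CpG dyad. Local density is the count of CG
occurrences whose C lies within +/-300 bp of the focal position (window
truncated at chromosome ends, focal dyad included); only forward-strand
dyads are counted, one per dyad. CGIs are merged before 2 kb shores are
built, shores exclude island sequence, and CGI takes precedence over
shore. Gene annotation uses TSS overlap (1 bp TSS by default, flank
configurable) before gene body, else intergenic. PMD/HMD domains and
ChromHMM states are assigned independently. Set enrichment is a per-label
2x2 Fisher exact test of a query set against its background universe,
two-sided for genome annotations and one-sided (greater) for chromatin
states, with fold change reported as (query fraction / background
fraction - 1) x 100.

## Slope-QTL mapping

Genotypes are additive minor-allele dosages; QC removes SNPs with call
rate < 0.98, MAF < 0.01 or exact Hardy-Weinberg p < 0.001 (full
enumeration of heterozygote counts at fixed allele counts). For every
cis pair (SNP within 1 Mb of the CpG) the individual slopes are regressed
on dosage; Benjamini-Hochberg correction is applied across all pairs
tested in the mode (cis and trans families are separate), significant at
q < 0.05. Pairs where dosage associates with the per-individual residual
sum of the trajectory fits (sum of squares by default; sum of absolute
residuals available behind a flag) are excluded as variance-QTLs, since
a SNP disrupting probe hybridisation inflates fit dispersion without a
genuine trajectory effect.

Conditional analysis resolves linked SNPs per CpG: the lead SNP is the
smallest p (ties broken by distance, then id); remaining SNPs are
re-tested against the residuals of the model containing all selected
SNPs, Bonferroni-corrected within the CpG, iterating until no addition.
Candidates correlating with a selected SNP at |r| > 0.95 are never added
— at that collinearity the residual test carries no separable signal.
Surviving pairs are validated with a pooled per-observation model
beta ~ age + G + age:G; on balanced noise-free data the interaction
coefficient equals the slope-regression effect exactly, and their rank
correlation exceeds 0.977 on the synthetic study design.

The local-effect profile normalises each lead SNP's effect on CpGs within
+/-1 kb by the lead-pair effect and averages in 50 bp bins of signed
distance; the null band comes from 1,000 permutations of the genotype
vector across individuals, which preserves the correlation structure of
neighbouring CpG slopes while breaking the genotype association.

## Density-variance analyses

Spearman correlations are reported with the t-approximation p-value on
n-2 degrees of freedom. Heteroscedasticity uses the studentized (Koenker)
Breusch-Pagan test: OLS of the response on the predictor, then n * R^2 of
the auxiliary regression of squared residuals on the predictor, referred
to chi-square(1). Inter-individual slope variance depends strongly
(parabolically) on the mean methylation level, so before comparisons it
is normalised by assigning probes to 20 equal-count bins of mean beta
(populations differ by at most one; ties broken by stable input order)
and subtracting the bin median; equal-width binning is available as an
option. Normalisation preserves within-bin ordering.

## The synthetic cohort generator

The generator is first-class, tested code and defines the study
conditions used throughout:

- **Design.** 600 individuals, waves at mean ages 69.6/72.6/76.3/79.3
  years, 351 with four and 249 with three measurements. Wave ages are
  drawn as wave mean + N(0, 0.8 y), with ordering enforced; the default
  allocation of which wave the 3-wave individuals miss (40/22/49/138)
  reproduces per-wave observation totals of 560/578/551/462. The wave
  dropped is configurable because real missingness patterns vary.
- **Betas.** beta = clamp(b0 + u_i + s_i (age - 70) + c . p + eps, 0, 1),
  with random intercepts u ~ N(0, tau^2) (default tau = 0.03, a typical
  between-individual offset on the beta scale), per-individual slopes
  s = m + beta_QTL * G + N(0, sigma_s^2) (default sigma_s = 0.002
  beta/year), optional per-CpG cell-loading terms, and measurement noise
  sigma_e = 0.01, about the technical replicate noise of Infinium arrays.
  Clamping after noise keeps betas in [0, 1]. Intercepts are parameterised
  at 70 years so b0 is the baseline level near study entry.
- **Genotypes.** Hardy-Weinberg draws at the stated MAF; each designated
  QTL CpG has one causal SNP placed within 10 kb, mirroring the observed
  proximity of lead SNPs to their CpGs.
- **Cell proportions.** Softmax of per-individual linear-in-age Gaussian
  latents, guaranteeing simplex validity while drifting approximately
  linearly; baselines give realistic blood fractions (~57% neutrophils,
  ~31% lymphocytes). Counts are scaled by a total white-cell count around
  6.5 x 10^9/L.
- **Genome.** CpG-free random background with dense island-like blocks
  (CpG every 10 bp) and isolated sparse CpGs, so true local density is
  computable by exhaustively scanning the string; CGI/gene/PMD/ChromHMM
  tracks are laid over the layout.
- **Reference profiles.** k cell types with discriminating CpGs near 0/1
  in one type, plus Dirichlet mixtures of known weights.

What the generator does **not** emulate: IDAT intensities, type I/II
probe chemistry biases, batch effects, relatedness, non-linear
trajectories, spatial correlation of methylation along the genome, and
age-dependent measurement error. Passing tests therefore demonstrate the
correctness and calibration of the estimators under the stated generative
model, not robustness to those real-data artefacts.

## Problem sizes and numerical choices

The test suite runs the full 600-individual design where the property
depends on it (estimator equivalence at 2,000 CpGs; effect-method
agreement at 500 pairs; null QTL scans at 1,000 CpGs x 5,000 SNPs over 20
replicates; effect recovery over 50 replicates) and an 80-individual
version of the same design for unit tests. Degenerate inputs are handled
explicitly: zero-variance slope sets report p = 0 (nonzero mean, flagged)
or p = 1 (zero mean); constant dosage after complete-case filtering skips
the pair; a constant predictor rejects a correlation; mixed-model
non-convergence flags the CpG without aborting. All randomness flows
through numpy Generators seeded from a single integer, and pipeline
reruns with the same config and seed are byte-identical.

## Open design choices taken

- "Residual sum" in the variance-QTL filter is the residual sum of
  squares of each individual fit by default; sum of absolute residuals is
  available behind a flag.
- Lead-SNP ties at equal p go to the nearest SNP, then lexicographic id.
- Conditional analysis iterates to convergence rather than stopping after
  one round, and reports the round each SNP entered.
- Equal bins for variance normalisation are equal-count (quantile) bins;
  equal-width is exposed as an option.
- The local-effect profile normalises by the lead-pair effect and
  permutes genotype vectors across individuals for its null.
- Bin medians for variance normalisation are computed on all supplied
  probes, not only significant ones.
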