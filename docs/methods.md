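# Methods

## Scope and design

The package implements four heritability designs over one synthetic data
spine, so that each estimator can be validated against generating truth
rather than against restricted registry data.  The family-pedigree (FP) and
identity-by-descent (IBD) designs work on relative pairs; GREML and LD-score
regression (LDSC) work on (near-)unrelated samples.  All estimators are
scikit-learn-style classes (`FamilyACE`, `IBDAE`, `BivariateACE`, `GREML`,
`LDScoreRegression`) with module-level functional wrappers.

## Synthetic data generator

**Pedigrees.**  An extended family is three generations: one founder
grandparent couple, two sibling parents each mated to an unrelated founder,
and one phenotyped sibship per parent couple — so the leaf generation
contains full-sibling pairs within sibships and first-cousin pairs across
them.  Twin pairs (MZ/DZ) are placed in sibships at configurable rates.
Pair classification runs over the leaf generation (the study cohort):
ancestors exist to establish relationships, exactly as in a registry
design where only one generation is phenotyped.

**Genotypes.**  Biallelic founder genotypes are drawn at frequencies uniform
on a MAF range and gene-dropped: each child inherits one grandparental origin
per block of `block_len` SNPs from each parent.  Blocks are independent (no
centimorgan map): this is sufficient to give realized sibling sharing a mean
of 0.5 and a spread controlled by the number of blocks (SD ≈
`sqrt(1/8 / n_blocks)`, e.g. ≈ 0.027 for 200 blocks), which is all the IBD
design needs.  MZ twins receive identical genotypes.  Optional LD is created
by composing founder haplotypes from a small ancestral pool per block
(`n_ancestral_haplotypes`, default 20 where used); optional population
stratification assigns whole families to one of two subpopulations and
diverges allele frequencies by per-SNP Balding–Nichols draws (parameter
`fst`), applied either to founder draws directly or — when the pool provides
LD — by resampling a fraction (`strat_resample`, default 0.2) of pool
alleles around the pool's realized frequencies.

**Phenotypes.**  Per family, cohort trait vectors are drawn jointly with
component covariance `K ⊗ C_A + Q ⊗ C_C + I ⊗ C_E`, where `K` is the
expected-relatedness matrix, `Q` the environment-sharing matrix (siblings
and twins 1, cousins `rho_c_cousin`), and `C_k` the trait covariance implied
by the variance fractions and the cross-trait correlation matrices `R_A`,
`R_C`, `R_E`.  This reproduces the pairwise moments
`Cov(P₁,P₂) = a² r_g + c² r_c` and their bivariate analogues exactly.  In
`snp_mode` the A component is instead `Σ_j w_ij β_j` over standardized
dosages with per-SNP effects correlated `R_A` across traits; realized
genetic values are rescaled so each trait's SNP heritability equals `var_a`
exactly, which keeps recovery tests sharp at moderate sample sizes.

**Registry panel.**  Latent traits are re-expressed as 11 yearly values over
ages 35–45: income and wealth are exponentiated to a positive kroner-like
scale with multiplicative yearly noise and nonpositive entries at
`zero_rate` (wealth may go negative); occupational prestige is a noisy score
clipped to a SIOPS-like 16–78 range; education is a nondecreasing yearly
attainment series in years of schooling (constant when `noise_sd` is zero).
Preprocessing then inverts this: natural log after setting nonpositive
monetary values to one, window averaging, highest attainment for education,
OLS residualization on sex, z-scoring.

**What the generator does not emulate:** realistic human LD maps and
recombination hotspots, assortative mating, imputation error, X chromosome,
selective participation, measurement artefacts specific to tax registers.
Passing recovery tests therefore demonstrates correctness of the estimators
under the stated model, not robustness to these real-data features.

## Estimators

**FP ACE/AE.**  Each pair contributes a bivariate-normal likelihood with
common variance `v = s_a + s_c + s_e` and cross-member covariance
`s_a r_g + s_c r_c`.  Every such covariance is exchangeable
(`[[S, B], [B, S]]`), so the sum/difference transform block-diagonalizes it
and the likelihood vectorizes over pairs even when `r_g` varies per pair
(the IBD case).  Variance components are optimized on their natural scale
with nonnegativity bounds (L-BFGS-B); the cousin `r_c` is either fixed or a
free parameter in [0, 1].  Fits at a bound are flagged (`boundary`), not
hidden.  Standardized fractions (`a² = s_a/v`, …) are reported with
delta-method standard errors from the numerically evaluated observed
information.  Pairs are treated as independent — a pseudo-likelihood, since
one person belongs to several pairs of an extended family; this leaves point
estimates consistent but makes information-based SEs somewhat
anticonservative, so a family-clustered sandwich SE is available
(`robust_se="family"`).  DZ twins are pooled with full siblings
(`r_g = 0.5`, `r_c = 1`); cousin `r_c` is restricted to [0, 1] (an
environment-sharing proportion).

**Bivariate fits** parameterize the component correlations `r_A`, `r_C`,
`r_E` directly (not via a Cholesky factor), so the quantities of interest
carry their own observed-information SEs.  Correlations are bounded at
±0.9999: the Gaussian likelihood is unbounded on the singular boundary
(e.g. duplicated traits), and the offset keeps the covariance invertible
while changing estimates by less than any reported precision; estimates
within 2×10⁻³ of ±1 are flagged as boundary fits.  Component correlations
whose variance is estimated at zero are reported as unestimable rather than
NaN-propagated.  Starting values for correlations are the empirical
within-person cross-trait correlation.

**IBD AE.**  As FP but with per-pair empirical `r̂_g` (clipped to [0, 1])
from the within-family robust kinship estimator
`φ̂ = (N_het,both − 2 N_opp-hom) / (N_het(1) + N_het(2))`; pairs with fewer
than `min_informative_snps` (default 1,000) heterozygous sites in the
denominator are flagged unestimable.  Zero variance in `r̂_g` across pairs is
an explicit identifiability error.

**GREML.**  Restricted likelihood of `Var(y) = A σg² + I σε²` on the
orthogonal complement of the fixed-effect design, rotated onto the
eigenbasis of the projected GRM, where it separates into independent normal
scalars; the total variance is profiled out, leaving a bounded 1-D search
over `h²`.  SEs come from the observed information in `(σg², σε²)`.
Negative GRM eigenvalues (possible after subsetting) are shifted with a
warning.  The bivariate version shares the rotation and fits 2×2 genetic and
residual blocks per eigenvalue, with `r_g` a direct parameter.

**GWAS scan.**  Per-SNP OLS of the phenotype on dosage with covariates
projected out, vectorized over SNP chunks.  This is a deliberate desk-scale
stand-in for a sparse-GRM mixed-model solver; the deviation is recorded in
the run metadata of every report bundle.

**LD scores and LDSC.**  `ℓ_j` sums bias-adjusted squared correlations
`r² − (1 − r²)/(n − 2)` over an index window (default 200 SNPs; the
synthetic map is block-based, so a window spanning one block suffices).
The regression of χ² on `N ℓ / M` is iteratively reweighted
(`w ∝ 1/(1 + N h² ℓ/M)²`) with delete-one block-jackknife SEs over
contiguous SNP blocks (default 200 blocks).  Negative fitted `h²` is
reported with a flag, never clipped.  The cross-trait version regresses
`z₁z₂` on `√(N₁N₂) ℓ / M` and normalizes by the two slope heritabilities;
its jackknife recomputes all three regressions per deleted block.

**Stratification and the intercept.**  Under the resampling-based
stratification option, confounding inflates the intercept (the designed
behavior); because resampling couples a SNP's realized differentiation with
attenuation of its LD, the slope is not interpretable under stratification
and nothing is claimed about it there.  Calibration of slope and intercept
is established in the unstratified setting.

**Relative pruning** is greedy: repeatedly drop the sample with the most
above-cutoff GRM partners (ties broken by sample order) until no
off-diagonal exceeds the cutoff.  The default cutoff of 0.025 matches
registry-scale SNP counts (~10⁶ SNPs, GRM noise SD ~0.001).  At desk scale
the GRM noise SD is `≈ 1/√m` (≈ 0.014 at m = 5,000), so a 0.025 cutoff would
discard most of a truly unrelated sample; desk-scale configurations should
set the cutoff to several noise SDs (the demo uses 0.2), and the recovery
tests fit GREML on samples that are unrelated by construction.

## Correlation structure and PCA

Pairwise bivariate fits fill the 4×4 indicator matrices per source
(phenotypic, A, C, E).  Pairwise estimates need not cohere into a PSD
matrix; non-PSD assemblies are projected by eigenvalue clipping with
rescaling to a unit diagonal, and the maximum entry change is recorded.
PCA is an eigendecomposition with loading signs fixed so each component's
largest-magnitude loading is positive.  Parallel analysis uses the
95th-percentile rule against eigenvalues of same-shape uncorrelated normal
data.  The permutation test permutes each variable independently; axis
significance is sequential (an axis counts only if all larger axes are
significant — otherwise the smallest axis triggers false positives by
construction), and variable contributions are tested via squared structure
coefficients (loading² × eigenvalue).  Bootstrap CIs are parametric by
default (draw `n_effective` observations from a zero-mean normal with the
estimated correlation; 10,000 replicates by default), with an
observation-resampling mode when raw data are available.  `n_effective` is
the number of informative pairs (family methods) or the analysis sample size
(SNP methods).  Note the usual ordered-eigenvalue bias: under a truly
uncorrelated truth the first component's bootstrap CI sits above 1/p.

## Problem sizes

Recovery checks run at: FP-ACE ≈ 20,000 sibling + 20,000 cousin + 2,000 MZ
pairs; IBD-AE 10,000 sibling pairs × 10,000 SNPs; GREML n = 2,000 ×
m = 5,000; LDSC n = 5,000 × m = 20,000; bivariate family ≈ 8,800 families
and cross-trait LDSC n = 5,000 × m = 16,000.  These sizes make the 2-SE
recovery bands a few percentage points wide while keeping a full test run in
minutes; the pipeline demo in the test suite is smaller still (hundreds of
families) and is checked for structure and determinism, not tight recovery.

## Numerical choices

Uniform variates for genotype sampling are drawn in float32 chunks
(Bernoulli thresholds lose nothing at that precision, and the chunking
bounds temporary memory).  Optimizations use L-BFGS-B with moment-based
starting values and one restart on non-convergence; numerical Hessians use
central differences with relative step 1e-4 and pseudo-inverse fallback.
ML estimates at the natural-scale bounds are flagged; their SEs should be
read with the usual boundary caveats.  All generators and analyses are
deterministic for a fixed seed.

## Known limitations

Pseudo-likelihood SEs for overlapping pairs (see above); no dominance or
sex-limitation models; pairwise (not joint 4-trait) bivariate decomposition,
so assembled component matrices can need PSD projection; OLS association
ignores relatedness (use on unrelated samples only); LDSC at desk scale has
wide jackknife bands because the synthetic LD score distribution is blocky;
official education/occupation code conversion tables are not bundled — a toy
mapping is provided and real tables are user-supplied TSVs.
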