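# sesherit

Heritability of the "big four" socioeconomic indicators — educational
attainment, occupational prestige, income and wealth — estimated four ways
from one codebase, with a synthetic-data generator that makes every estimator
checkable by parameter recovery.

Registry and biobank studies of socioeconomic status compare family-based and
SNP-based heritability under consistent sampling: a **family-pedigree (FP)
ACE model** on twin, full-sibling and first-cousin pairs; an
**identity-by-descent (IBD) AE model** on siblings using their *realized*
genome sharing; **GREML** (restricted maximum likelihood on a genomic
relatedness matrix of near-unrelated individuals); and **LD-score
regression** on GWAS summary statistics.  The real linked registry data
behind such studies is access-restricted, so this package pairs the four
estimators with a generator that gene-drops genotypes through simulated
extended families and draws multi-trait phenotypes with known
additive-genetic (A), shared-environment (C) and non-shared (E) structure —
including the cousin shared-environment correlation that family designs
usually fix by assumption.

## The models

For a pair of relatives with genetic correlation `r_g` and
shared-environment correlation `r_c`, the FP ACE model is

    Var(P)        = a² + c² + e²
    Cov(P₁, P₂)   = a² · r_g + c² · r_c

with `r_g` = 1 (MZ twins), 0.5 (full siblings, DZ twins), 0.125 (first
cousins) from the pedigree, sibling `r_c` = 1, and cousin `r_c` either fixed
or estimated as a free parameter; `h² = a²` on the standardized scale.  The
IBD design drops C and replaces `r_g` by each sibling pair's estimated
genome-sharing proportion (KING-robust within-family estimator), so
heritability is identified by variation in realized sharing around 0.5.
GREML fits `Var(y) = A σg² + I σε²` with `A = WW′/N` the GRM of standardized
dosages and `h² = σg²/(σg² + σε²)`.  LD-score regression fits
`E[χ²] = 1 + N·a + N h² ℓ_j / M`: the slope estimates SNP heritability and
the intercept absorbs confounding.  Bivariate versions of the family, IBD
and SNP models give cross-trait A/C/E correlations, which are assembled into
4×4 indicator correlation matrices and analyzed by PCA with Horn's parallel
analysis, permutation tests and bootstrap confidence intervals.

## Worked example

```python
import sesherit as sh
from sesherit.pedigree import pairs_to_frame

# 5,000 three-generation families (cousin links) + 2,000 MZ twin families
ped = sh.Pedigree.concat([
    sh.simulate_pedigree(sh.FamilyConfig(5000, 2, cousin_links=True), seed=11),
    sh.simulate_pedigree(sh.FamilyConfig(2000, 2, twin_rate_mz=1.0,
                                         cousin_links=False), seed=13,
                         id_prefix="T"),
])
model = sh.TraitModel(var_a=0.30, var_c=0.25, var_e=0.45, rho_c_cousin=0.59)
pheno = sh.simulate_phenotypes(ped, model, seed=14)

pairs = pairs_to_frame(ped.classify_pairs())
table = sh.build_pair_table(pairs, pheno, "education", covariates=())

free = sh.fit_univariate(table, "education", "ACE", rc_cousin="free",
                         covariates=())
fixed = sh.fit_univariate(table, "education", "ACE", rc_cousin=0.0,
                          covariates=())
print(f"free rho_c : a2={free.a2:.3f} c2={free.c2:.3f} rho_c={free.rho_c:.3f}"
      f" (SE {free.se['rho_c']:.3f})")
print(f"rho_c = 0  : a2={fixed.a2:.3f} c2={fixed.c2:.3f}")
```

Output from this exact run:

```
free rho_c : a2=0.231 c2=0.284 rho_c=0.557 (SE 0.037)
rho_c = 0  : a2=0.501 c2=0.104
```

Read: when the cousin shared-environment correlation is estimated (here
0.557, generating value 0.59) instead of assumed zero, the heritability
estimate drops from 0.50 to 0.23 — the same attenuation the free-parameter
family design shows on real registry data.  `sensitivity_sweep` traces the
full curve of a², c², e² across assumed cousin correlations from 0 to 1 in
steps of 0.05.

`run_full_analysis(AnalysisConfig(...))` drives everything — panel
preprocessing (log-transform of monetary traits after setting nonpositive
values to one, 11-year averaging, highest-attainment education), pair
classification, all enabled estimators, bivariate fits, matrix assembly and
the PCA battery — and writes a report bundle (TSV tables + JSON manifest)
that is byte-identical under a fixed seed.

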