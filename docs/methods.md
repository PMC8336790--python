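# Methods

## Overview

The package implements an adiposity-PRS association analysis as a chain of
small, separately testable operations: variant QC → in-cohort per-variant
GWAS → catalog filtering and LD pruning → unweighted scoring → covariate-
adjusted association models → effect-size clustering. A synthetic-cohort
generator with a known genetic architecture supplies inputs, so every
statistical property asserted by the test suite is checked against either
a closed form, a brute-force oracle, or Monte-Carlo truth.

## Synthetic cohort

**Genotypes.** Each variant belongs to an LD block. Per haplotype, a block
is a multivariate-Gaussian latent vector thresholded at Φ⁻¹(1 − f) so the
alt-allele indicator has frequency f; the dosage is the sum of two
independent haplotypes, giving hard calls in {0, 1, 2}. The latent
correlation for a pair with target allele-level r² is solved numerically
from the bivariate-normal orthant probability, so empirical MAF is exact in
expectation and within-block dosage r² converges to the target (tested at
n = 50,000 within ±0.05). Targets that exceed the maximum attainable
correlation for a frequency pair raise a validation error. Cross-block r²
is ~0. Fractional (imputed) dosages and missingness are an I/O concern and
are exercised by the VCF round-trip tests, keeping the simulator's LD
algebra exact.

**Phenotypes.** Six z-scale phenotypes (BMI, WC, HC, BF%, SAT, VAT) follow
a linear model: per-variant additive effects on centred dosages, shared
latent factors (an "overall adiposity" and a "central fat" factor that
induce the strong BMI–WC–SAT–BF% and weaker VAT phenotypic correlations),
age and sex slopes, a per-family random intercept, and Gaussian noise.
z-values map to natural units through fixed (mean, SD) pairs chosen to
mirror a middle-aged, predominantly female cohort with high adiposity
burden (e.g. BMI 32.2 ± 7.2 kg/m², SAT 2336 ± 1015 cm³, VAT 839 ± 383 cm³).
WHR is derived as WC/HC, never simulated directly, so the ratio constraint
holds identically. Visit 1 carries anthropometrics only (with small
re-measurement noise, ages 5 years younger); CT and bioimpedance measures
exist only at visit 2, which mirrors how such cohorts are measured and
exercises the per-trait analysis-visit selection.

**Default architecture.** 12 BMI, 8 WC-adj-BMI, 10 WHR-adj-BMI and 6 BF%
variants with effects of roughly 0.05–0.13 z per allele, encoding the
structure the analysis is designed to detect: BMI/BF% variants load on
BF%/SAT (weakly on VAT), WHR variants on VAT with WC up / HC down and no
SAT effect. Effects of ~0.1 z per allele over ~10 loci put each own-trait
PRS association at p ≪ 10⁻⁵ for n = 2420, so end-to-end sign patterns are
stable across seeds. Twelve null variants serve as catalog false
positives; two of them sit in LD (r² = 0.5) with a causal variant so
pruning always has work to do, and the catalog generator assigns false
entries preferentially from such linked decoys. A further 200 independent
null "backbone" variants stand in for the genome-wide panel from which
ancestry PCs are computed — with a panel of only tens of variants the top
PCs would absorb individual trait loci rather than ancestry, which no
genome-wide PCA does. Family structure defaults to 600 families
(intercept SD 0.25 z); sample accounting defaults to 2554 visit-2
participants with 10 pregnancy and 124 missing/implausible exclusions,
i.e. 2420 analysed.

**Determinism.** One global seed is split into fixed per-stage substreams
(SeedSequence keys), so re-running any stage reproduces bit-identical
output and stages can be re-run independently.

## QC and I/O

Dosages are read from VCF with the DS FORMAT field taking precedence and
hard GT calls as fallback; a DS outside [0, 2] is an error, missing
genotypes become NaN. Variant QC retains MAF ≥ 1%, call rate ≥ 90%,
HWE p > 10⁻⁶ and imputation r² > 0.9. The HWE test is the 1-df chi-square
goodness-of-fit without continuity correction, computed on hard calls
(rounded dosages); monomorphic variants return p = 1 by convention. MAF is
mean dosage / 2 over non-missing samples, folded at 0.5. The retained set
is the conjunction of all filters, hence independent of evaluation order,
and QC is idempotent. "Biologically implausible" phenotype values are an
input flag set by the fixture generator, not recomputed — no published
plausibility rules exist to implement.

## Risk sets

Catalog admission requires reported p ≤ 5×10⁻⁸. LD is the squared Pearson
correlation of in-sample dosages over pairwise-complete samples
(composite LD); an external reference panel is deliberately not used, so
the package is self-contained offline. Pruning is greedy sentinel
selection: entries are walked in priority order — reported p ascending,
then study size descending, then study year descending, then variant key —
and kept iff r² < 0.1 against every kept entry (r² ≥ 0.1 counts as
linked). The priority key is a documented convention: no precedence among
"lower p, larger, more recent" is canonical, and p-value first is the
strongest signal proxy while the full key makes pruning deterministic and
input-order invariant. Approach 2 keeps entries whose in-cohort beta,
re-oriented to the published effect allele, is positive; approach 3 adds
in-cohort p < 0.05. Filtering precedes pruning, so the three sets are
nested.

## Per-variant GWAS

Each variant is tested by OLS of the inverse-normal phenotype on dosage
plus covariates (age, sex, optional ancestry PCs; inverse-normal BMI for
WC and WHR), with a Wald t test on residual df. BMI and WC use visit-1
phenotypes (larger n), other traits visit 2. Missing dosages are
mean-imputed per variant. A genetic-relationship-matrix mixed model is
intentionally not reproduced for this screen: its role here is a sign and
nominal-significance filter, the synthetic cohort's family structure is
weak (intercept SD 0.25 z), and the interface accepts arbitrary extra
covariates so a mixed solver can drop in. The implementation is
closed-form normal-equations OLS (cross-checked against statsmodels to
1e-10) because Monte-Carlo calibration tests run tens of thousands of
fits.

## PRS

Alignment is by ref/alt identity: effect allele = alt uses g, = ref uses
2 − g, otherwise the variant is excluded with an audit entry.
Strand-ambiguous (A/T, C/G) variants are retained with a warning by
default (synthetic data has no strand ambiguity; real catalogs do), with a
strict mode to exclude them. Missing dosages impute at twice the in-sample
effect-allele frequency — catalog frequencies would be ancestry-mismatched.
Scores are raw allele counts, not standardized, so a downstream slope
reads "per 1 trait-increasing allele"; β×100 is 100× the raw slope on the
outcome z-score scale.

## Association models

The inverse-normal transform uses the Blom offset,
Φ⁻¹((r − 3/8)/(n + 1/4)), with average ranks for ties — the standard in
genetic epidemiology — applied after sample exclusions within the analysis
visit. Ancestry PCs are the SVD of the dosage matrix standardized by 2f
and √(2f(1−f)), monomorphic variants excluded, signs fixed for
determinism. The headline model is OLS of the outcome z-score on the raw
PRS plus age, sex, 10 PCs (± inverse-normal BMI), fitted via statsmodels;
95% CIs use t quantiles. Incremental R² is R²(full) − R²(covariates only)
— the interpretable reading of "variance predicted by the PRS" when the
marginal/incremental choice is ambiguous. The mixed alternative adds a
family random intercept, fitted by REML profiling of the single variance
ratio λ = σ²_family/σ²_resid: for fixed λ the block-diagonal marginal
covariance inverts in closed form per family, leaving a one-dimensional
criterion optimized by bounded search on log λ with the λ = 0 boundary
checked explicitly; λ may also be fixed by the caller (λ = 0 reproduces
OLS exactly). The linear model is the primary report; the mixed model is
secondary, as the two agree closely when family effects are modest.
Two-sided p-values throughout; no multiple-testing correction is applied
at the association stage.

## Effect clustering

The effect matrix holds β×100 of each selected variant (rows, annotated by
source trait) against BF%, SAT, VAT and VSR (columns); rows missing any
estimate are dropped with an audit entry. Ward linkage uses the
Lance-Williams recursion on squared Euclidean distances with heights on
the distance scale (the Ward.D2 convention, √(2·ΔESS)), ties broken by the
smallest (left, right) cluster-index pair. The implementation is
exhaustive-oracle-tested at n ≤ 6 and cross-checked against
scipy.cluster.hierarchy on tie-free data. Rendered output includes a TSV
of the matrix in *canonical* leaf order — children of every merge are
arranged by their subtree's smallest row label — which makes the ordering
a function of tree topology and labels only, hence invariant to input row
permutation and machine-checkable without image parsing. Both rows and
columns are clustered by default; column clustering is configurable.

## Problem sizes and numerical choices

Monte-Carlo checks use: 100 draws for the PRS, pruning and Ward oracles;
2000 null replicates of n = 500 for type-I error (accepted band
0.040–0.060); 200 cohorts of n = 2420 for slope recovery (20 equal-effect
variants of 0.08 z per allele, unit total variance, implied β×100 = 8.0)
and CI coverage (band 0.92–0.98); 100 default-architecture cohorts of
n = 2420 for the fat-depot sign pattern (≥ 90% positive). These sizes make
the full suite and the acceptance script each run in well under half an
hour on one CPU while keeping binomial noise several-fold smaller than
the accepted bands. Latent-correlation root finding uses Brent's method at
1e-10 tolerance with an LRU cache; PSD of block latent correlations is
enforced via Cholesky with 1e-10 jitter; REML uses 1e-12 xatol on log λ.

## What passing tests do and do not show

The generator produces hard-call, biallelic, autosomal-style variants with
rectangular LD blocks, no strand ambiguity, no population structure unless
requested, Gaussian phenotypes and missingness injected only where a test
needs it. Passing tests therefore demonstrate correctness of the
algorithms and calibration of the statistics under the stated generating
model — not robustness to real-data pathologies (reference-panel LD
mismatch, admixture-driven confounding beyond what PCs capture,
non-additive effects, informative missingness, phenotype measurement
artifacts). The fat-depot association pattern recovered end to end is
encoded in the generator's architecture; its recovery validates the
pipeline's plumbing and power at the stated effect sizes, and says nothing
about any real cohort.

## Known limitations

- In-sample composite LD replaces reference-panel LD; pruned sets can
  differ from panel-based pruning near the r² threshold.
- The per-variant screen is OLS, not a GRM mixed model; with strong
  cryptic relatedness its p-values would be anticonservative.
- The REML profile assumes a single random intercept; nested or crossed
  random effects are out of scope.
- Weighted scores, LDpred-style shrinkage and score cross-validation are
  deliberately excluded; sex-stratified models are not implemented.
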