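# adiposcore

Unweighted polygenic risk scores (PRS) for adiposity traits and their
association with body-fat-distribution phenotypes, packaged as a tested,
reusable pipeline with a synthetic-cohort generator.

## The scientific problem

Common variants for body mass index (BMI), waist circumference adjusted for
BMI (WC<sub>adjBMI</sub>), waist-hip ratio adjusted for BMI
(WHR<sub>adjBMI</sub>) and body-fat percentage (BF%) were discovered mostly
in European-ancestry GWAS. Whether those loci transfer to African-ancestry
individuals — and whether they act on subcutaneous (SAT) or visceral (VAT)
fat depots — is a question about *where* genetically driven fat gain is
deposited. The analysis implemented here:

1. extracts genome-wide-significant published variants per trait
   (p ≤ 5×10⁻⁸) and LD-prunes them to independent sentinels
   (pairwise r² < 0.1, prioritizing lower p, larger and more recent
   studies);
2. builds three nested risk sets per trait — all pruned loci (approach 1),
   those with directional replication in an in-cohort per-variant GWAS
   (approach 2), and those adding nominal in-cohort significance p < 0.05
   (approach 3);
3. scores each individual with an **unweighted** PRS,
   `PRS_i = Σ_j d_ij`, where `d_ij ∈ [0, 2]` is the dosage of the
   trait-increasing allele at locus j (equal weights are robust to
   effect-size transfer across ancestries and winner's-curse bias);
4. regresses each inverse-normal-transformed outcome (BF%, SAT, VAT,
   VAT:SAT ratio) on the PRS with age, sex, 10 ancestry PCs and optionally
   BMI as covariates (linear or family-random-intercept mixed model),
   reporting `β×100` = percent change in outcome z-score per risk allele;
5. clusters the per-variant `β×100` effect matrix with Ward's
   minimum-variance method to visualize which fat depot each variant group
   acts on.

Controlled-access cohort data are not required: `synthetic_cohort`
generates block-LD genotypes, family-clustered covariates and phenotypes
from an explicit linear architecture in which BMI/BF% variants act on
subcutaneous fat and WHR variants on visceral fat, with a variant catalog
carrying ground-truth labels, so every stage is testable end to end.

## Worked example

```bash
adiposcore all --seed 1 --outdir run1
```

or equivalently `adiposcore.run_pipeline(seed=1, outdir="run1")`. This
simulates 2554 visit-2 participants, flags 10 pregnancy and 124
missing/implausible exclusions (2420 analysed), applies variant QC
(MAF ≥ 1%, call rate ≥ 90%, HWE p > 10⁻⁶, imputation r² > 0.9), runs the
per-variant GWAS, builds risk sets, scores and fits the models. Risk-set
sizes at seed 1 show the approach-1 ⊇ 2 ⊇ 3 nesting, e.g. BMI 15/13/11 and
BF% 9/7/5 variants.

`run1/prs_validation.tsv` — each PRS against its own phenotype (approach 1):

| PRS | β×100 | p | incremental R² |
|---|---|---|---|
| BMI | 8.48 | 1.3×10⁻²² | 0.038 |
| WC_adjBMI | 6.15 | 5.3×10⁻¹¹ | 0.013 |
| WHR_adjBMI | 5.26 | 4.1×10⁻⁸ | 0.012 |
| BF% | 8.05 | 9.5×10⁻¹⁶ | 0.021 |

Every score predicts its own trait (validity check). A β×100 of 8.48 means
each additional BMI-increasing allele raises the BMI z-score by 0.085.

`run1/associations.tsv` — cross-trait associations (approach 1, no BMI
adjustment) show the fat-depot pattern the generator encodes: the BMI-PRS
predicts SAT strongly (β×100 = 7.0, p = 2×10⁻²⁰) but VSR negatively
(β×100 = −3.0), while the WHR-PRS predicts VAT (β×100 = 8.0, p = 7×10⁻¹⁹)
and VSR (β×100 = 5.6) but not SAT (β×100 = 0.04, p = 0.97). Genetically
driven overall fat gain is subcutaneous; central-fat-patterning loci are
visceral.

`run1/effect_matrix_ordered.tsv` holds the Ward-clustered per-variant
effect matrix (rows in canonical dendrogram order, so the clustering is
machine-checkable), and `run1/effect_heatmap.png` the rendered heatmap.

## Layout

- `src/adiposcore/synthetic_cohort.py` — architecture spec, block-LD
  genotype/phenotype/catalog simulation, exclusion fixtures
- `src/adiposcore/io_and_qc.py` — VCF dosage I/O (DS with GT fallback),
  HWE test, variant QC, sample exclusions
- `src/adiposcore/risk_sets.py` — catalog admission, in-sample LD, greedy
  sentinel pruning, approaches 1–3
- `src/adiposcore/internal_gwas.py` — per-variant covariate-adjusted OLS
  replication screen
- `src/adiposcore/prs_engine.py` — allele alignment and unweighted scoring
- `src/adiposcore/association_stats.py` — inverse-normal transform,
  ancestry PCs, PRS association models, REML random intercept, Spearman
  matrix
- `src/adiposcore/effect_clustering.py` — effect matrix, Ward linkage,
  heatmap rendering
- `src/adiposcore/pipeline.py`, `cli.py` — orchestration, config
  validation, run manifest

See `docs/methods.md` for the statistical methods, default parameters and
known limitations.
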