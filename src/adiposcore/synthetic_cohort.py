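"""Synthetic adiposity cohort with a known multi-trait genetic architecture.

Generates block-LD genotypes, family-clustered covariates and six adiposity
phenotypes (BMI, WC, HC, BF%, SAT, VAT; WHR derived as WC/HC) from an
explicit linear architecture, plus a published-variant catalog with ground
truth, so that every downstream stage — QC, internal GWAS, risk-set
filtering, PRS and association models — can be tested end to end without
any controlled-access data.

The default architecture encodes the qualitative structure the analysis is
designed to detect: BMI- and BF%-associated variants act predominantly on
overall/subcutaneous fat (BF%, SAT), while WHR-associated variants act on
visceral fat (VAT) and central fat patterning.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .io_and_qc import COHORT_COLUMNS, GenotypeMatrix, VariantRecord

#: Simulated phenotypes, in column order of ArchitectureSpec.effects.
PHENOTYPES = ["BMI", "WC", "HC", "BFpct", "SAT", "VAT"]

#: Natural-unit (mean, SD) used to map z-scale phenotypes to measured units,
#: chosen to mirror a middle-aged, predominantly female African American
#: cohort with high adiposity burden.
PHENO_SCALE = {
    "BMI": (32.2, 7.2),     # kg/m^2
    "WC": (102.9, 16.2),    # cm
    "HC": (114.7, 14.9),    # cm
    "BFpct": (38.2, 9.9),   # percent
    "SAT": (2335.8, 1014.7),  # cm^3
    "VAT": (839.4, 383.1),    # cm^3
}

#: PRS source traits a catalog variant can be labelled with.
PRS_TRAITS = ["BMI", "WCadjBMI", "WHRadjBMI", "BFpct"]

#: Study-condition sample accounting: visit-2 participants, pregnancy
#: exclusions, missing/implausible exclusions (analysed n = 2420).
DEFAULT_N_VISIT2 = 2554
DEFAULT_N_PREGNANT = 10
DEFAULT_N_MISSING = 124

_ALLELE_PAIRS = [("A", "G"), ("C", "T"), ("G", "A"), ("T", "C"), ("A", "C"), ("G", "T")]


class ArchitectureError(ValueError):
    """Invalid ArchitectureSpec (message names the offending field/variant)."""


@dataclass(frozen=True)
class VariantSpec:
    """One simulated variant: alt-allele frequency, LD-block membership and
    the within-block target dosage r^2."""

    maf: float
    block_id: str
    target_r2: float = 0.0
    source_trait: str | None = None  # PRS trait this variant "belongs" to; None = null

    def validate(self, idx: int) -> None:
        if not 0.0 < self.maf < 1.0:
            raise ArchitectureError(f"variant {idx} ({self.block_id}): maf {self.maf} not in (0,1)")
        if not 0.0 <= self.target_r2 < 1.0:
            raise ArchitectureError(f"variant {idx} ({self.block_id}): target_r2 {self.target_r2} not in [0,1)")
        if self.source_trait is not None and self.source_trait not in PRS_TRAITS:
            raise ArchitectureError(f"variant {idx}: unknown source_trait {self.source_trait}")


@dataclass
class ArchitectureSpec:
    """Full generating model for one synthetic cohort.

    ``effects`` is n_variants x n_phenotypes on the z-score scale (per alt
    allele); ``factor_loadings`` is n_factors x n_phenotypes and injects
    shared (environmental) correlation across phenotypes;
    ``covariate_effects`` holds per-phenotype age (per year, centred at 60)
    and male-sex slopes; ``family_sd`` is the SD of the per-family,
    per-phenotype shared intercept.
    """

    n_samples: int
    n_families: int
    family_sd: float
    variants: list[VariantSpec]
    effects: np.ndarray
    factor_loadings: np.ndarray = field(default_factory=lambda: np.zeros((0, len(PHENOTYPES))))
    covariate_effects: dict = field(default_factory=lambda: {
        "age": np.zeros(len(PHENOTYPES)), "sex_male": np.zeros(len(PHENOTYPES))})
    residual_sd: np.ndarray = field(default_factory=lambda: np.ones(len(PHENOTYPES)))
    seed: int = 0
    phenotypes: list[str] = field(default_factory=lambda: list(PHENOTYPES))

    def __post_init__(self) -> None:
        self.effects = np.atleast_2d(np.asarray(self.effects, dtype=float))
        self.factor_loadings = np.atleast_2d(np.asarray(self.factor_loadings, dtype=float))
        self.residual_sd = np.asarray(self.residual_sd, dtype=float)
        self.validate()

    def validate(self) -> None:
        if self.n_samples <= 0 or self.n_families <= 0:
            raise ArchitectureError("n_samples and n_families must be positive")
        if self.family_sd < 0:
            raise ArchitectureError("family_sd must be >= 0")
        for i, v in enumerate(self.variants):
            v.validate(i)
        P = len(self.phenotypes)
        if self.effects.shape != (len(self.variants), P):
            raise ArchitectureError(
                f"effects shape {self.effects.shape} != ({len(self.variants)}, {P})")
        if self.factor_loadings.shape[1] != P:
            raise ArchitectureError("factor_loadings second dimension mismatch")
        if self.residual_sd.shape != (P,) or np.any(self.residual_sd <= 0):
            raise ArchitectureError("residual_sd must be positive, one per phenotype")

    @property
    def n_variants(self) -> int:
        return len(self.variants)


def _rng(seed: int, stage: int) -> np.random.Generator:
    """Deterministic per-stage substream of a single global seed."""
    return np.random.default_rng(np.random.SeedSequence((int(seed), int(stage))))


# ---------------------------------------------------------------------------
# Genotypes: thresholded latent-Gaussian haplotypes per LD block
# ---------------------------------------------------------------------------

@functools.lru_cache(maxsize=4096)
def _latent_rho(f_i: float, f_j: float, target_r2: float) -> float:
    """Latent bivariate-normal correlation whose thresholded indicators
    (thresholds Phi^-1(1-f)) have allele-level correlation sqrt(target_r2).

    Solved by numerical root finding on the bivariate normal orthant
    probability. Raises when the target correlation exceeds the maximum
    attainable for the given frequency pair.
    """
    if target_r2 == 0.0:
        return 0.0
    r = float(np.sqrt(target_r2))
    p11_target = r * np.sqrt(f_i * (1 - f_i) * f_j * (1 - f_j)) + f_i * f_j
    if p11_target > min(f_i, f_j) + 1e-12:
        raise ArchitectureError(
            f"target_r2 {target_r2} unattainable for allele frequencies {f_i}, {f_j}")
    a, b = stats.norm.ppf(1 - f_i), stats.norm.ppf(1 - f_j)

    def orthant(rho: float) -> float:
        mvn = stats.multivariate_normal(mean=[0, 0], cov=[[1, rho], [rho, 1]],
                                        allow_singular=True)
        # P(X > a, Y > b) = P(X <= -a, Y <= -b) by symmetry
        return float(mvn.cdf([-a, -b]))

    lo, hi = -0.999, 0.99995
    f_lo, f_hi = orthant(lo) - p11_target, orthant(hi) - p11_target
    if f_hi < 0:  # target sits at the comonotone boundary
        return hi
    if f_lo > 0:
        raise ArchitectureError("orthant probability cannot reach target")
    return float(optimize.brentq(lambda rho: orthant(rho) - p11_target, lo, hi,
                                 xtol=1e-10))


def simulate_genotypes(spec: ArchitectureSpec) -> GenotypeMatrix:
    """Draw hard-call dosages {0,1,2} with the spec's allele frequencies and
    within-block LD.

    Each haplotype is a multivariate-Gaussian latent vector per block,
    thresholded at Phi^-1(1 - f) so the alt-allele indicator has frequency f
    and the pairwise allele correlation hits sqrt(target_r2); the dosage is
    the sum of two independent haplotypes. Cross-block r^2 is ~0.
    """
    spec.validate()
    rng = _rng(spec.seed, 1)
    n, m = spec.n_samples, spec.n_variants

    blocks: dict[str, list[int]] = {}
    for j, v in enumerate(spec.variants):
        blocks.setdefault(v.block_id, []).append(j)

    dosages = np.empty((n, m), dtype=float)
    for bid, idx in blocks.items():
        k = len(idx)
        corr = np.eye(k)
        for a in range(k):
            for b in range(a + 1, k):
                vi, vj = spec.variants[idx[a]], spec.variants[idx[b]]
                t = min(vi.target_r2, vj.target_r2)
                corr[a, b] = corr[b, a] = _latent_rho(vi.maf, vj.maf, t)
        try:
            chol = np.linalg.cholesky(corr + 1e-10 * np.eye(k))
        except np.linalg.LinAlgError as exc:
            raise ArchitectureError(f"block {bid}: latent correlation not PSD") from exc
        thr = np.array([stats.norm.ppf(1 - spec.variants[j].maf) for j in idx])
        total = np.zeros((n, k))
        for _hap in range(2):
            z = rng.standard_normal((n, k)) @ chol.T
            total += (z > thr)
        dosages[:, idx] = total

    variants = []
    for j, v in enumerate(spec.variants):
        ref, alt = _ALLELE_PAIRS[j % len(_ALLELE_PAIRS)]
        variants.append(VariantRecord(
            chrom=str(j % 22 + 1), pos=10_000 + 1_000 * j, ref=ref, alt=alt,
            imputation_quality=1.0))
    sample_ids = [f"S{i:05d}" for i in range(n)]
    return GenotypeMatrix(sample_ids=sample_ids, variants=variants, dosages=dosages)


# ---------------------------------------------------------------------------
# Phenotypes
# ---------------------------------------------------------------------------

def simulate_phenotypes(genotypes: GenotypeMatrix, spec: ArchitectureSpec) -> pd.DataFrame:
    """Generate the cohort table (visits 1 and 2) from the linear architecture.

    Each z-scale phenotype is
    ``sum_j effect_j * (g_j - 2 f_j) + factor terms + covariate terms +
    family intercept + noise``; z values are mapped to natural units via
    PHENO_SCALE and WHR is derived as WC/HC. Visit 1 carries anthropometrics
    only (with small re-measurement noise, age 5 years younger); CT and
    bioimpedance measures (SAT, VAT, BF%) exist at visit 2 only.
    """
    if genotypes.n_samples != spec.n_samples:
        raise ArchitectureError(
            f"genotype samples {genotypes.n_samples} != spec n_samples {spec.n_samples}")
    if genotypes.n_variants != spec.n_variants:
        raise ArchitectureError("genotype/effects variant count mismatch")
    rng = _rng(spec.seed, 2)
    n, P = spec.n_samples, len(spec.phenotypes)

    freqs = np.array([v.maf for v in spec.variants])
    g_centred = genotypes.dosages - 2 * freqs
    genetic = g_centred @ spec.effects

    n_factors = spec.factor_loadings.shape[0]
    factors = rng.standard_normal((n, n_factors)) if n_factors else np.zeros((n, 0))
    shared = factors @ spec.factor_loadings

    age2 = rng.uniform(35, 84, size=n)
    male = rng.random(n) < 0.369
    cov = (np.outer(age2 - 60.0, spec.covariate_effects["age"])
           + np.outer(male.astype(float), spec.covariate_effects["sex_male"]))

    fam_of = np.arange(n) % spec.n_families
    fam_effects = rng.normal(0.0, spec.family_sd, size=(spec.n_families, P))
    fam = fam_effects[fam_of]

    noise = rng.standard_normal((n, P)) * spec.residual_sd
    z = genetic + shared + cov + fam + noise

    nat = np.empty_like(z)
    for p, name in enumerate(spec.phenotypes):
        mean, sd = PHENO_SCALE[name]
        nat[:, p] = mean + sd * z[:, p]
    col = {name: nat[:, p] for p, name in enumerate(spec.phenotypes)}
    col["SAT"] = np.clip(col["SAT"], 0.0, None)
    col["VAT"] = np.clip(col["VAT"], 0.0, None)

    meas = rng.standard_normal((n, 3)) * 0.05  # visit-1 re-measurement noise (z units)
    rows = []
    for visit in (1, 2):
        df = pd.DataFrame({
            "sample_id": genotypes.sample_ids,
            "family_id": [f"F{f:04d}" for f in fam_of],
            "sex": np.where(male, "male", "female"),
            "age": age2 - (5.0 if visit == 1 else 0.0),
            "visit": visit,
        })
        if visit == 1:
            df["BMI"] = col["BMI"] + PHENO_SCALE["BMI"][1] * meas[:, 0]
            df["WC"] = col["WC"] + PHENO_SCALE["WC"][1] * meas[:, 1]
            df["HC"] = col["HC"] + PHENO_SCALE["HC"][1] * meas[:, 2]
            df["BFpct"] = np.nan
            df["SAT"] = np.nan
            df["VAT"] = np.nan
        else:
            df["BMI"], df["WC"], df["HC"] = col["BMI"], col["WC"], col["HC"]
            df["BFpct"], df["SAT"], df["VAT"] = col["BFpct"], col["SAT"], col["VAT"]
        df["WHR"] = df["WC"] / df["HC"]
        df["pregnancy_excluded"] = False
        df["missing_implausible"] = False
        rows.append(df)
    out = pd.concat(rows, ignore_index=True)
    return out[COHORT_COLUMNS]


def flag_exclusions(ct: pd.DataFrame, n_pregnant: int, n_missing: int,
                    seed: int = 0) -> pd.DataFrame:
    """Set disjoint pregnancy / missing-implausible flags on visit-2 rows.

    Pregnancy flags are placed on female rows only. Raises when the request
    exceeds the available visit-2 rows (or female rows, for pregnancy).
    """
    ct = ct.copy()
    v2 = np.flatnonzero((ct["visit"] == 2).to_numpy())
    if n_pregnant + n_missing > len(v2):
        raise ValueError(
            f"requested {n_pregnant}+{n_missing} flags but only {len(v2)} visit-2 rows")
    rng = _rng(seed, 3)
    females = v2[(ct["sex"].to_numpy()[v2] == "female")]
    if n_pregnant > len(females):
        raise ValueError("not enough female visit-2 rows for pregnancy flags")
    preg = rng.choice(females, size=n_pregnant, replace=False)
    remaining = np.setdiff1d(v2, preg)
    miss = rng.choice(remaining, size=n_missing, replace=False)
    ct.loc[ct.index[preg], "pregnancy_excluded"] = True
    ct.loc[ct.index[miss], "missing_implausible"] = True
    return ct


def make_exclusion_fixture(n_visit2: int = DEFAULT_N_VISIT2,
                           n_pregnant: int = DEFAULT_N_PREGNANT,
                           n_missing: int = DEFAULT_N_MISSING,
                           seed: int = 0) -> pd.DataFrame:
    """Minimal visit-2 cohort table with exactly the requested, disjoint
    exclusion flags; defaults reproduce the study's sample accounting
    (2554 visit-2 participants, 10 pregnancy and 124 missing/implausible
    exclusions, 2420 analysed)."""
    if n_pregnant < 0 or n_missing < 0 or n_pregnant + n_missing > n_visit2:
        raise ValueError("flag counts exceed table size or are negative")
    rng = _rng(seed, 4)
    male = rng.random(n_visit2) < 0.369
    if n_pregnant > 0:
        male[:n_pregnant] = False  # guarantee enough females for pregnancy flags
    ct = pd.DataFrame({
        "sample_id": [f"S{i:05d}" for i in range(n_visit2)],
        "family_id": [f"F{i % max(1, n_visit2 // 4):04d}" for i in range(n_visit2)],
        "sex": np.where(male, "male", "female"),
        "age": rng.uniform(35, 84, size=n_visit2),
        "visit": 2,
    })
    for name in ("BMI", "WC", "HC", "BFpct", "SAT", "VAT"):
        mean, sd = PHENO_SCALE[name]
        ct[name] = mean + sd * rng.standard_normal(n_visit2)
    ct["SAT"] = ct["SAT"].clip(lower=0.0)
    ct["VAT"] = ct["VAT"].clip(lower=0.0)
    ct["WHR"] = ct["WC"] / ct["HC"]
    ct["pregnancy_excluded"] = False
    ct["missing_implausible"] = False
    ct = ct[COHORT_COLUMNS]
    return flag_exclusions(ct, n_pregnant, n_missing, seed=seed)


# ---------------------------------------------------------------------------
# Catalog
# ---------------------------------------------------------------------------

def _trait_direction(spec: ArchitectureSpec, j: int) -> float:
    """Signed effect of variant j on its source trait, in trait units.

    For ratio traits (WHRadjBMI) the direction is the derivative of WC/HC at
    the population means; for the others it is the direct z-scale effect.
    """
    v = spec.variants[j]
    e = dict(zip(spec.phenotypes, spec.effects[j]))
    if v.source_trait == "BMI":
        return e["BMI"]
    if v.source_trait == "WCadjBMI":
        return e["WC"]
    if v.source_trait == "BFpct":
        return e["BFpct"]
    if v.source_trait == "WHRadjBMI":
        wc_m, wc_s = PHENO_SCALE["WC"]
        hc_m, hc_s = PHENO_SCALE["HC"]
        return e["WC"] * wc_s / hc_m - e["HC"] * hc_s * wc_m / hc_m**2
    raise ArchitectureError(f"variant {j} has no source trait")


def simulate_catalog(genotypes: GenotypeMatrix, spec: ArchitectureSpec,
                     n_false: int = 0, seed: int = 0) -> list:
    """Build the published-variant catalog: every causal variant (effect
    allele = its trait-increasing allele, reported p below genome-wide
    significance) plus ``n_false`` null variants with fabricated provenance.
    Ground-truth causality labels are kept for filter testing.
    """
    from .risk_sets import CatalogEntry

    rng = _rng(seed, 5)
    null_idx = [j for j, v in enumerate(spec.variants) if v.source_trait is None]
    if n_false > len(null_idx):
        raise ArchitectureError(
            f"n_false={n_false} exceeds {len(null_idx)} available null variants")

    def draw_meta() -> tuple[float, int, int, str]:
        p = 10.0 ** rng.uniform(-30.0, np.log10(5e-8))
        year = int(rng.integers(2007, 2021))
        n_study = int(10 ** rng.uniform(4.0, 5.85))
        tag = rng.choice(["EUR", "EUR", "EUR", "MULTI", "AFR"])
        return p, year, n_study, str(tag)

    entries = []
    for j, v in enumerate(spec.variants):
        if v.source_trait is None:
            continue
        rec = genotypes.variants[j]
        direction = _trait_direction(spec, j)
        effect_allele = rec.alt if direction >= 0 else rec.ref
        p, year, n_study, tag = draw_meta()
        entries.append(CatalogEntry(
            key=rec.key, effect_allele=effect_allele, trait=v.source_trait,
            reported_p=p, study_year=year, study_n=n_study, ancestry_tag=tag,
            is_causal=True))
    # decoys in multi-variant LD blocks come first: a published false positive
    # tagging a real locus is exactly what pruning must absorb
    block_size: dict[str, int] = {}
    for v in spec.variants:
        block_size[v.block_id] = block_size.get(v.block_id, 0) + 1
    linked = [j for j in null_idx if block_size[spec.variants[j].block_id] > 1]
    lone = [j for j in null_idx if block_size[spec.variants[j].block_id] == 1]
    pool = (list(rng.permutation(linked)) if linked else []) + \
           (list(rng.permutation(lone)) if lone else [])
    chosen = pool[:n_false]
    for k, j in enumerate(chosen):
        rec = genotypes.variants[j]
        p, year, n_study, tag = draw_meta()
        entries.append(CatalogEntry(
            key=rec.key, effect_allele=rec.alt if rng.random() < 0.5 else rec.ref,
            trait=PRS_TRAITS[k % len(PRS_TRAITS)], reported_p=p,
            study_year=year, study_n=n_study, ancestry_tag=tag, is_causal=False))
    return entries


# ---------------------------------------------------------------------------
# Default architecture (the study conditions)
# ---------------------------------------------------------------------------

def default_architecture(n_samples: int = DEFAULT_N_VISIT2, seed: int = 0,
                         n_families: int = 600, family_sd: float = 0.25,
                         n_backbone: int = 200) -> ArchitectureSpec:
    """Default generating model.

    Variant groups (all effects in z-units per alt allele):

    * 12 BMI variants: overall adiposity — BMI, WC, BF%, SAT, weak VAT;
    * 8 WC-adj-BMI variants: central girth — WC plus both fat depots;
    * 10 WHR-adj-BMI variants: fat patterning — WC up, HC down, VAT up,
      no SAT effect (so VSR rises);
    * 6 BF% variants: body-fat — BF% and SAT, weak BMI;
    * 12 null variants (catalog false positives / LD partners);
    * ``n_backbone`` further independent null variants standing in for the
      genome-wide backbone from which ancestry PCs are computed (with a
      panel of only tens of variants the top PCs would absorb individual
      trait loci instead of ancestry, which no genome-wide PCA does).

    Two of the causal variants share an LD block with a null partner at
    r^2 = 0.5 to exercise pruning. One shared latent "overall adiposity"
    factor and one "central fat" factor reproduce the strong BMI-WC-SAT-BF%
    and weaker VAT phenotypic correlations.
    """
    rng = np.random.default_rng(np.random.SeedSequence((int(seed), 6)))
    phenos = PHENOTYPES
    variants: list[VariantSpec] = []
    effects: list[np.ndarray] = []

    def add(source: str | None, e: dict, maf: float, block: str, r2: float = 0.0) -> None:
        variants.append(VariantSpec(maf=maf, block_id=block, target_r2=r2,
                                    source_trait=source))
        effects.append(np.array([e.get(p, 0.0) for p in phenos]))

    def mafs(k: int) -> np.ndarray:
        return np.round(rng.uniform(0.10, 0.50, size=k), 3)

    for i, f in enumerate(mafs(12)):
        add("BMI", {"BMI": 0.10, "WC": 0.08, "HC": 0.06, "BFpct": 0.08,
                    "SAT": 0.09, "VAT": 0.05}, f, f"bmi{i}")
    for i, f in enumerate(mafs(8)):
        add("WCadjBMI", {"WC": 0.10, "HC": 0.02, "SAT": 0.07, "VAT": 0.07,
                         "BMI": 0.03}, f, f"wc{i}")
    for i, f in enumerate(mafs(10)):
        add("WHRadjBMI", {"WC": 0.05, "HC": -0.05, "VAT": 0.10, "SAT": 0.0,
                          "BMI": 0.0}, f, f"whr{i}")
    for i, f in enumerate(mafs(6)):
        add("BFpct", {"BFpct": 0.13, "SAT": 0.10, "BMI": 0.05, "WC": 0.03,
                      "VAT": 0.02}, f, f"bf{i}")
    # null variants; two sit in LD with a causal partner to exercise pruning
    null_mafs = mafs(12)
    add(None, {}, float(variants[0].maf), "bmi0", r2=0.5)
    add(None, {}, float(variants[12].maf), "wc0", r2=0.5)
    for i, f in enumerate(null_mafs[2:]):
        add(None, {}, f, f"null{i}")
    for i, f in enumerate(np.round(rng.uniform(0.05, 0.50, size=n_backbone), 3)):
        add(None, {}, float(f), f"bb{i}")
    # LD partners need their causal anchor to carry the same target_r2
    variants[0] = VariantSpec(maf=variants[0].maf, block_id="bmi0", target_r2=0.5,
                              source_trait="BMI")
    variants[12] = VariantSpec(maf=variants[12].maf, block_id="wc0", target_r2=0.5,
                               source_trait="WCadjBMI")

    loadings = np.array([
        #  BMI   WC    HC  BFpct  SAT   VAT
        [0.72, 0.62, 0.55, 0.65, 0.70, 0.35],   # overall adiposity
        [0.00, 0.22, -0.05, 0.00, 0.05, 0.48],  # central/visceral fat
    ])
    covariate_effects = {
        "age": np.array([-0.002, 0.004, 0.000, 0.004, 0.000, 0.010]),
        "sex_male": np.array([-0.30, 0.10, -0.40, -1.00, -0.60, 0.20]),
    }
    eff = np.vstack(effects)
    freqs = np.array([v.maf for v in variants])
    gen_var = (2 * freqs * (1 - freqs))[:, None] * eff**2
    explained = gen_var.sum(axis=0) + (loadings**2).sum(axis=0) + family_sd**2
    residual_sd = np.sqrt(np.clip(1.0 - explained, 0.25, None))

    return ArchitectureSpec(
        n_samples=n_samples, n_families=n_families, family_sd=family_sd,
        variants=variants, effects=eff, factor_loadings=loadings,
        covariate_effects=covariate_effects, residual_sd=residual_sd, seed=seed)


# ---------------------------------------------------------------------------
# Serialization (flat key=value with tabular sections)
# ---------------------------------------------------------------------------

def save_architecture(spec: ArchitectureSpec, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("[global]\n")
        for k in ("n_samples", "n_families", "family_sd", "seed"):
            fh.write(f"{k}={getattr(spec, k)}\n")
        fh.write("phenotypes=" + ",".join(spec.phenotypes) + "\n")
        fh.write("residual_sd=" + ",".join(f"{x:.10g}" for x in spec.residual_sd) + "\n")
        fh.write("age_effects=" + ",".join(f"{x:.10g}" for x in spec.covariate_effects["age"]) + "\n")
        fh.write("sex_male_effects=" + ",".join(f"{x:.10g}" for x in spec.covariate_effects["sex_male"]) + "\n")
        fh.write("[variants]\n")
        fh.write("maf\tblock_id\ttarget_r2\tsource_trait\t"
                 + "\t".join(f"effect_{p}" for p in spec.phenotypes) + "\n")
        for j, v in enumerate(spec.variants):
            fh.write(f"{v.maf:.10g}\t{v.block_id}\t{v.target_r2:.10g}\t"
                     f"{v.source_trait or '.'}\t"
                     + "\t".join(f"{x:.10g}" for x in spec.effects[j]) + "\n")
        fh.write("[factor_loadings]\n")
        for row in spec.factor_loadings:
            fh.write("\t".join(f"{x:.10g}" for x in row) + "\n")


def load_architecture(path: str) -> ArchitectureSpec:
    sections: dict[str, list[str]] = {}
    current = None
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("[") and line.endswith("]"):
                current = line[1:-1]
                sections[current] = []
            else:
                sections[current].append(line)
    glob = dict(line.split("=", 1) for line in sections["global"])
    phenotypes = glob["phenotypes"].split(",")
    header = sections["variants"][0].split("\t")
    variants, effects = [], []
    for line in sections["variants"][1:]:
        cells = dict(zip(header, line.split("\t")))
        variants.append(VariantSpec(
            maf=float(cells["maf"]), block_id=cells["block_id"],
            target_r2=float(cells["target_r2"]),
            source_trait=None if cells["source_trait"] == "." else cells["source_trait"]))
        effects.append([float(cells[f"effect_{p}"]) for p in phenotypes])
    loadings = np.array([[float(x) for x in line.split("\t")]
                         for line in sections.get("factor_loadings", [])])
    if loadings.size == 0:
        loadings = np.zeros((0, len(phenotypes)))
    return ArchitectureSpec(
        n_samples=int(glob["n_samples"]), n_families=int(glob["n_families"]),
        family_sd=float(glob["family_sd"]), variants=variants,
        effects=np.array(effects), factor_loadings=loadings,
        covariate_effects={
            "age": np.array([float(x) for x in glob["age_effects"].split(",")]),
            "sex_male": np.array([float(x) for x in glob["sex_male_effects"].split(",")]),
        },
        residual_sd=np.array([float(x) for x in glob["residual_sd"].split(",")]),
        seed=int(glob["seed"]), phenotypes=phenotypes)
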