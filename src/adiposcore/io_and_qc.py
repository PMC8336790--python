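"""Genotype/phenotype I/O and quality control.

Reads imputed dosages from VCF (``DS`` FORMAT field, falling back to hard
``GT`` calls), writes them back out, and applies the standard variant-level
QC used for imputed GWAS data — minor allele frequency, call rate,
Hardy-Weinberg equilibrium and imputation quality — plus the sample-level
exclusions (pregnancy, missing/implausible phenotypes) applied before any
association analysis.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

#: Cohort-table column schema shared across modules.
COHORT_COLUMNS = [
    "sample_id", "family_id", "sex", "age", "visit",
    "BMI", "WC", "HC", "WHR", "BFpct", "SAT", "VAT",
    "pregnancy_excluded", "missing_implausible",
]


class VcfParseError(ValueError):
    """Malformed VCF content (message carries the offending record)."""


@dataclass(frozen=True)
class VariantRecord:
    """One biallelic variant with the QC metadata attached to it."""

    chrom: str
    pos: int  # 1-based, as in VCF
    ref: str
    alt: str
    imputation_quality: float = 1.0  # imputation r^2 in [0, 1]

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref}) at {self.chrom}:{self.pos}")
        if not 0.0 <= self.imputation_quality <= 1.0:
            raise ValueError(f"imputation_quality outside [0,1]: {self.imputation_quality}")

    @property
    def key(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"


@dataclass
class GenotypeMatrix:
    """Samples x variants dosage matrix.

    ``dosages[i, j]`` is the expected alt-allele count of sample ``i`` at
    variant ``j``, in [0, 2]; ``nan`` marks a missing genotype.
    """

    sample_ids: list[str]
    variants: list[VariantRecord]
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        n, m = len(self.sample_ids), len(self.variants)
        if self.dosages.shape != (n, m):
            raise ValueError(f"dosage shape {self.dosages.shape} != ({n}, {m})")
        if len(set(self.sample_ids)) != n:
            raise ValueError("duplicate sample ids")
        keys = [v.key for v in self.variants]
        if len(set(keys)) != m:
            raise ValueError("duplicate variant keys")
        with np.errstate(invalid="ignore"):
            if np.any((self.dosages < 0) | (self.dosages > 2)):
                raise ValueError("dosage outside [0, 2]")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def variant_index(self) -> dict[str, int]:
        return {v.key: j for j, v in enumerate(self.variants)}

    def dosage_for(self, key: str) -> np.ndarray:
        return self.dosages[:, self.variant_index[key]]

    def subset_variants(self, keep: list[int]) -> "GenotypeMatrix":
        return GenotypeMatrix(
            sample_ids=list(self.sample_ids),
            variants=[self.variants[j] for j in keep],
            dosages=self.dosages[:, keep].copy(),
        )


@dataclass(frozen=True)
class QcConfig:
    """All thresholds of the analysis, with their conventional defaults.

    maf_min/call_rate_min/hwe_p_min gate array variants before imputation;
    imp_r2_min gates imputed dosages; gwas_sig is the genome-wide
    significance level used for catalog admission; ld_r2 the pruning
    threshold (pairs at r^2 >= ld_r2 count as linked); nominal_p the
    internal-replication significance level; n_pcs the number of ancestry
    principal components used as covariates.
    """

    maf_min: float = 0.01
    call_rate_min: float = 0.90
    hwe_p_min: float = 1e-6
    imp_r2_min: float = 0.9
    gwas_sig: float = 5e-8
    ld_r2: float = 0.1
    nominal_p: float = 0.05
    n_pcs: int = 10

    def __post_init__(self) -> None:
        for name in ("maf_min", "call_rate_min", "hwe_p_min", "imp_r2_min",
                     "gwas_sig", "ld_r2", "nominal_p"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} outside [0,1]: {v}")
        if self.maf_min > 0.5:
            raise ValueError("maf_min above 0.5")
        if self.n_pcs < 0:
            raise ValueError("n_pcs negative")


# ---------------------------------------------------------------------------
# VCF round trip
# ---------------------------------------------------------------------------

def write_vcf(gm: GenotypeMatrix, path: str) -> None:
    """Write a minimal VCF 4.2 with DS and GT FORMAT fields and an R2 INFO tag.

    Dosages are rounded to 3 decimals; GT carries the nearest hard call
    (used by readers without DS support). Missing dosages become ``./.``.
    """
    chroms = sorted({v.chrom for v in gm.variants}, key=str)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=R2,Number=1,Type=Float,Description="Imputation quality r-squared">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Estimated alt allele dosage">\n')
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(gm.sample_ids) + "\n")
        order = sorted(range(gm.n_variants),
                       key=lambda j: (str(gm.variants[j].chrom), gm.variants[j].pos))
        for j in order:
            v = gm.variants[j]
            cells = []
            for d in gm.dosages[:, j]:
                if math.isnan(d):
                    cells.append("./.:.")
                else:
                    hard = int(round(d))
                    gt = {0: "0/0", 1: "0/1", 2: "1/1"}[hard]
                    cells.append(f"{gt}:{d:.3f}")
            fh.write(f"{v.chrom}\t{v.pos}\t{v.key}\t{v.ref}\t{v.alt}\t.\tPASS\t"
                     f"R2={v.imputation_quality:.4f}\tGT:DS\t" + "\t".join(cells) + "\n")


def read_dosages(path: str) -> GenotypeMatrix:
    """Read a VCF into a GenotypeMatrix.

    The DS FORMAT field takes precedence; when absent the dosage is the
    alt-allele count from GT. Missing genotypes become ``nan``. A DS value
    outside [0, 2] raises.
    """
    from cyvcf2 import VCF

    try:
        vcf = VCF(path, gts012=True)
    except Exception as exc:  # cyvcf2 raises bare OSError/Exception on bad files
        raise VcfParseError(f"cannot open VCF {path}: {exc}") from exc
    samples = list(vcf.samples)
    variants: list[VariantRecord] = []
    cols: list[np.ndarray] = []
    for line_no, v in enumerate(vcf, start=1):
        if len(v.ALT) != 1:
            raise VcfParseError(f"record {line_no} ({v.CHROM}:{v.POS}) is not biallelic")
        r2 = v.INFO.get("R2")
        rec = VariantRecord(chrom=str(v.CHROM), pos=int(v.POS), ref=v.REF, alt=v.ALT[0],
                            imputation_quality=float(r2) if r2 is not None else 1.0)
        ds = v.format("DS")
        if ds is not None:
            col = np.asarray(ds, dtype=float).reshape(-1)
            col[~np.isfinite(col) | (col < -1)] = np.nan  # cyvcf2 missing sentinel
            bad = np.isfinite(col) & ((col < -1e-9) | (col > 2 + 1e-9))
            if bad.any():
                raise VcfParseError(
                    f"DS outside [0,2] at {rec.key} (record {line_no}): "
                    f"{col[bad][:3].tolist()}")
            col = np.clip(col, 0.0, 2.0)
        else:
            gt = np.asarray(v.gt_types, dtype=float)  # 0/1/2, 3 = unknown
            gt[gt == 3] = np.nan
            col = gt
        variants.append(rec)
        cols.append(col)
    dosages = (np.column_stack(cols) if cols
               else np.empty((len(samples), 0)))
    return GenotypeMatrix(sample_ids=samples, variants=variants, dosages=dosages)


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------

def hwe_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Hardy-Weinberg goodness-of-fit p-value (1-df chi-square, no continuity
    correction) from genotype counts. Monomorphic input returns 1 by
    convention."""
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("negative genotype count")
    n = n_AA + n_Aa + n_aa
    if n == 0:
        raise ValueError("empty genotype counts")
    p = (2 * n_AA + n_Aa) / (2 * n)
    if p in (0.0, 1.0):
        return 1.0
    exp = np.array([n * p * p, 2 * n * p * (1 - p), n * (1 - p) * (1 - p)])
    obs = np.array([n_AA, n_Aa, n_aa], dtype=float)
    chi2 = float(np.sum((obs - exp) ** 2 / exp))
    return float(stats.chi2.sf(chi2, df=1))


def variant_stats(gm: GenotypeMatrix) -> pd.DataFrame:
    """Per-variant call rate, alt-allele frequency, MAF and HWE p-value.

    MAF is mean dosage / 2 over non-missing samples, folded to [0, 0.5];
    HWE is computed on hard calls (dosages rounded to the nearest integer).
    """
    rows = []
    for j, v in enumerate(gm.variants):
        d = gm.dosages[:, j]
        ok = ~np.isnan(d)
        call_rate = float(ok.mean()) if d.size else 0.0
        if ok.any():
            f_alt = float(d[ok].mean() / 2.0)
            hard = np.rint(d[ok]).astype(int)
            counts = np.bincount(hard, minlength=3)
            hwe_p = hwe_test(int(counts[2]), int(counts[1]), int(counts[0]))
        else:
            f_alt, hwe_p = np.nan, np.nan
        rows.append({
            "key": v.key, "call_rate": call_rate, "alt_freq": f_alt,
            "maf": min(f_alt, 1 - f_alt) if not math.isnan(f_alt) else np.nan,
            "hwe_p": hwe_p, "imputation_r2": v.imputation_quality,
        })
    return pd.DataFrame(rows, columns=["key", "call_rate", "alt_freq", "maf",
                                       "hwe_p", "imputation_r2"])


#: QC filters in audit-report order: (name, keep-predicate over the stats row).
_QC_FILTERS = (
    ("maf", lambda s, cfg: s["maf"] >= cfg.maf_min),
    ("call_rate", lambda s, cfg: s["call_rate"] >= cfg.call_rate_min),
    ("hwe", lambda s, cfg: s["hwe_p"] > cfg.hwe_p_min),
    ("imputation_r2", lambda s, cfg: s["imputation_r2"] > cfg.imp_r2_min),
)


def apply_variant_qc(gm: GenotypeMatrix, cfg: QcConfig | None = None
                     ) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Drop variants failing MAF >= 1%, call rate >= 90%, HWE p > 1e-6 or
    imputation r^2 > 0.9 (defaults; see QcConfig).

    Returns the filtered matrix and an audit table with one row per dropped
    variant and the (first, in fixed order) failed filter as ``reason`` plus
    all failed filters in ``failed``. The retained set is the conjunction of
    all filters, so it does not depend on evaluation order.
    """
    cfg = cfg or QcConfig()
    st = variant_stats(gm)
    keep: list[int] = []
    audit_rows = []
    for j, (_, s) in enumerate(st.iterrows()):
        failed = [name for name, pred in _QC_FILTERS if not pred(s, cfg)]
        if failed:
            audit_rows.append({"key": s["key"], "reason": failed[0],
                               "failed": ",".join(failed)})
            log.info("QC drop %s: %s", s["key"], ",".join(failed))
        else:
            keep.append(j)
    audit = pd.DataFrame(audit_rows, columns=["key", "reason", "failed"])
    return gm.subset_variants(keep), audit


def apply_sample_exclusions(ct: pd.DataFrame) -> pd.DataFrame:
    """Remove rows flagged ``pregnancy_excluded`` or ``missing_implausible``.

    The returned frame preserves row order; its length is the analysed
    sample size.
    """
    for col in ("pregnancy_excluded", "missing_implausible"):
        if col not in ct.columns:
            raise KeyError(f"cohort table lacks flag column {col!r}")
    mask = ~(ct["pregnancy_excluded"].astype(bool) | ct["missing_implausible"].astype(bool))
    out = ct.loc[mask].reset_index(drop=True)
    if out.empty:
        log.warning("all %d samples excluded", len(ct))
    return out
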