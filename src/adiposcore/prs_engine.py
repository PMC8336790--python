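"""Unweighted polygenic risk scores.

Each individual's score is the plain sum of trait-increasing allele dosages
over the risk set — every variant contributes with weight 1. The unweighted
choice trades a little in-ancestry precision for robustness to effect-size
transfer across ancestries, winner's-curse bias and demographic
confounding, which is what matters when applying European-discovered loci
to an African-ancestry cohort.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_and_qc import GenotypeMatrix, VariantRecord
from .risk_sets import CatalogEntry, RiskSet

log = logging.getLogger(__name__)

_AMBIGUOUS = {frozenset("AT"), frozenset("CG")}


class EmptyRiskSetError(ValueError):
    pass


@dataclass
class PrsVector:
    """Per-sample unweighted risk-allele sum, in the genotype matrix's
    sample order. Bounds: 0 <= score <= 2 * n_variants_used."""

    sample_ids: list[str]
    scores: np.ndarray
    trait: str
    approach: int
    n_variants_used: int
    audit: pd.DataFrame = field(default_factory=pd.DataFrame)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "sample_id": self.sample_ids, "trait": self.trait,
            "approach": self.approach, "score": self.scores,
            "n_variants_used": self.n_variants_used,
        })


def align_alleles(entry: CatalogEntry, rec: VariantRecord) -> str:
    """Orient a catalog entry against a genotype record.

    Returns ``"same"`` when the effect allele is the alt allele (score uses
    the dosage g), ``"flip"`` when it is the reference allele (score uses
    2 - g), ``"mismatch"`` when it is neither.
    """
    key_chrompos = entry.key.split(":")[:2]
    if [rec.chrom, str(rec.pos)] != key_chrompos:
        raise ValueError(f"entry {entry.key} and record {rec.key} differ in position")
    if entry.effect_allele == rec.alt:
        return "same"
    if entry.effect_allele == rec.ref:
        return "flip"
    return "mismatch"


def compute_prs(gm: GenotypeMatrix, rs: RiskSet,
                strict_ambiguous: bool = False) -> PrsVector:
    """Sum effect-allele dosages over the risk set for every sample.

    Missing dosages are replaced by twice the in-sample effect-allele
    frequency (catalog frequencies would be ancestry-mismatched).
    Strand-ambiguous (A/T, C/G) variants are kept with a warning by
    default — alignment here is by ref/alt identity, not strand — or
    excluded when ``strict_ambiguous``. Scores are raw allele counts, so a
    downstream slope reads "per 1 trait-increasing allele".
    """
    if not rs.entries:
        raise EmptyRiskSetError(f"risk set for {rs.trait} (approach {rs.approach}) is empty")
    index = gm.variant_index
    n = gm.n_samples
    scores = np.zeros(n)
    used = 0
    audit_rows = []

    def note(key: str, status: str, reason: str = "") -> None:
        audit_rows.append({"key": key, "status": status, "reason": reason})

    for e in rs.entries:
        if e.key not in index:
            note(e.key, "excluded", "absent_from_genotypes")
            continue
        j = index[e.key]
        rec = gm.variants[j]
        if frozenset((rec.ref, rec.alt)) in _AMBIGUOUS:
            if strict_ambiguous:
                note(e.key, "excluded", "strand_ambiguous")
                continue
            log.warning("strand-ambiguous variant %s retained", e.key)
        orientation = align_alleles(e, rec)
        if orientation == "mismatch":
            note(e.key, "excluded", "allele_mismatch")
            continue
        d = gm.dosages[:, j]
        miss = np.isnan(d)
        if miss.all():
            note(e.key, "excluded", "all_missing")
            continue
        eff = d if orientation == "same" else 2.0 - d
        f_eff = float(eff[~miss].mean() / 2.0)
        eff = np.where(miss, 2.0 * f_eff, eff)
        scores += eff
        used += 1
        note(e.key, "used", orientation)
    if used == 0:
        raise EmptyRiskSetError(
            f"no usable variants in risk set for {rs.trait} (approach {rs.approach})")
    return PrsVector(sample_ids=list(gm.sample_ids), scores=scores,
                     trait=rs.trait, approach=rs.approach, n_variants_used=used,
                     audit=pd.DataFrame(audit_rows, columns=["key", "status", "reason"]))
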