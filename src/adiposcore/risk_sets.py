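"""Risk-set construction: catalog filtering, in-sample LD and greedy pruning.

A published-variant catalog is reduced to one independent sentinel variant
per locus (pairwise dosage r^2 below 0.1), with sentinels prioritized by
reported p-value, then study size, then recency. Three nested risk sets are
produced per trait: all pruned genome-wide-significant loci (approach 1),
the subset with directional replication in the internal GWAS (approach 2),
and the subset adding nominal internal significance p < 0.05 (approach 3).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_and_qc import GenotypeMatrix, QcConfig

log = logging.getLogger(__name__)

TRAITS = ("BMI", "WCadjBMI", "WHRadjBMI", "BFpct")


class LdUndefinedError(ValueError):
    """LD requested against a constant dosage vector."""


@dataclass(frozen=True)
class CatalogEntry:
    """One published trait-increasing variant with the provenance used for
    sentinel prioritization."""

    key: str  # chrom:pos:ref:alt
    effect_allele: str
    trait: str
    reported_p: float
    study_year: int
    study_n: int
    ancestry_tag: str = "EUR"
    is_causal: bool | None = None  # ground truth, only set by the simulator

    def __post_init__(self) -> None:
        if self.trait not in TRAITS:
            raise ValueError(f"unknown trait {self.trait!r}")
        if not 0.0 < self.reported_p <= 1.0:
            raise ValueError(f"reported_p out of range: {self.reported_p}")

    @property
    def priority(self) -> tuple:
        """Sentinel ordering: lowest p, then largest study, then most recent,
        then variant key for determinism."""
        return (self.reported_p, -self.study_n, -self.study_year, self.key)


@dataclass
class RiskSet:
    """LD-pruned, approach-filtered variant list per trait: the PRS definition."""

    trait: str
    approach: int
    entries: list[CatalogEntry]
    audit: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def keys(self) -> list[str]:
        return [e.key for e in self.entries]


def compute_ld_r2(dosage_i: np.ndarray, dosage_j: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors over samples
    non-missing in both (composite, in-sample LD)."""
    x = np.asarray(dosage_i, dtype=float)
    y = np.asarray(dosage_j, dtype=float)
    if x.shape != y.shape:
        raise ValueError("dosage vectors differ in length")
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if x.size < 2 or np.ptp(x) == 0 or np.ptp(y) == 0:
        raise LdUndefinedError("constant or near-empty dosage vector")
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def admit_catalog(entries: list[CatalogEntry], cfg: QcConfig | None = None
                  ) -> list[CatalogEntry]:
    """Keep entries reported at genome-wide significance (p <= 5e-8)."""
    cfg = cfg or QcConfig()
    return [e for e in entries if e.reported_p <= cfg.gwas_sig]


def prune_by_ld(entries: list[CatalogEntry], gm: GenotypeMatrix,
                cfg: QcConfig | None = None, trait: str | None = None,
                approach: int = 1) -> RiskSet:
    """Greedy sentinel selection: walk entries in priority order and keep an
    entry iff its in-sample r^2 with every already-kept entry is below
    cfg.ld_r2 (pairs at exactly the threshold count as linked).

    Entries absent from the genotype matrix are skipped with an audit row;
    a constant dosage makes LD undefined and the pair is treated as
    unlinked, with a warning.
    """
    cfg = cfg or QcConfig()
    index = gm.variant_index
    kept: list[CatalogEntry] = []
    audit_rows = []
    for e in sorted(entries, key=lambda e: e.priority):
        if e.key not in index:
            audit_rows.append({"key": e.key, "status": "skipped",
                               "reason": "absent_from_genotypes", "sentinel_of": ""})
            continue
        d = gm.dosages[:, index[e.key]]
        linked_to = None
        for k in kept:
            try:
                r2 = compute_ld_r2(d, gm.dosages[:, index[k.key]])
            except LdUndefinedError:
                log.warning("LD undefined for %s vs %s; treated as unlinked",
                            e.key, k.key)
                continue
            if r2 >= cfg.ld_r2:
                linked_to = k.key
                break
        if linked_to is None:
            kept.append(e)
            audit_rows.append({"key": e.key, "status": "kept", "reason": "",
                               "sentinel_of": ""})
        else:
            audit_rows.append({"key": e.key, "status": "dropped", "reason": "ld",
                               "sentinel_of": linked_to})
    traits = {e.trait for e in entries}
    trait = trait or (traits.pop() if len(traits) == 1 else "mixed")
    return RiskSet(trait=trait, approach=approach, entries=kept,
                   audit=pd.DataFrame(audit_rows,
                                      columns=["key", "status", "reason", "sentinel_of"]))


def build_risk_set(catalog: list[CatalogEntry], internal, approach: int,
                   gm: GenotypeMatrix, cfg: QcConfig | None = None,
                   trait: str | None = None) -> RiskSet:
    """Assemble one trait's risk set under one filtering approach.

    Approach 1 keeps all genome-wide-significant catalog entries; approach 2
    keeps those whose internal effect-allele beta is positive (directional
    replication); approach 3 additionally requires internal p < nominal_p.
    LD pruning runs after the filter, so approach 3 ⊆ 2 ⊆ 1.
    """
    cfg = cfg or QcConfig()
    if approach not in (1, 2, 3):
        raise ValueError(f"approach must be 1, 2 or 3, got {approach}")
    entries = admit_catalog(catalog, cfg)
    if trait is not None:
        entries = [e for e in entries if e.trait == trait]
    if approach >= 2:
        if internal is None:
            raise ValueError("approach 2/3 requires internal GWAS results")
        by_key = {(r.key, r.trait): r for r in internal}
        filtered = []
        for e in entries:
            r = by_key.get((e.key, e.trait))
            if r is None:
                raise ValueError(f"internal GWAS result missing for {e.key} ({e.trait})")
            # internal betas are alt-oriented; re-orient to the effect allele
            _, _, ref, alt = e.key.split(":")
            if e.effect_allele == alt:
                beta_eff = r.beta
            elif e.effect_allele == ref:
                beta_eff = -r.beta
            else:
                log.warning("effect allele %s matches neither allele of %s; dropped",
                            e.effect_allele, e.key)
                continue
            if beta_eff <= 0:
                continue
            if approach == 3 and not (r.p < cfg.nominal_p):
                continue
            filtered.append(e)
        entries = filtered
    rs = prune_by_ld(entries, gm, cfg, trait=trait, approach=approach)
    return rs


# ---------------------------------------------------------------------------
# Catalog / risk-set TSV round trip
# ---------------------------------------------------------------------------

_CATALOG_COLS = ["key", "effect_allele", "trait", "reported_p", "study_year",
                 "study_n", "ancestry_tag", "is_causal"]


def write_catalog(entries: list[CatalogEntry], path: str) -> None:
    rows = [{c: getattr(e, c) for c in _CATALOG_COLS} for e in entries]
    df = pd.DataFrame(rows, columns=_CATALOG_COLS)
    df["is_causal"] = df["is_causal"].map(
        lambda v: "." if v is None else str(bool(v)))
    df.to_csv(path, sep="\t", index=False)


def read_catalog(path: str) -> list[CatalogEntry]:
    df = pd.read_csv(path, sep="\t", dtype={"is_causal": str})
    entries = []
    for _, r in df.iterrows():
        causal = None if r.get("is_causal", ".") in (".", None) else r["is_causal"] == "True"
        entries.append(CatalogEntry(
            key=r["key"], effect_allele=r["effect_allele"], trait=r["trait"],
            reported_p=float(r["reported_p"]), study_year=int(r["study_year"]),
            study_n=int(r["study_n"]), ancestry_tag=str(r["ancestry_tag"]),
            is_causal=causal))
    return entries


def write_risk_set(rs: RiskSet, path: str) -> None:
    audit = rs.audit.copy()
    audit.insert(0, "trait", rs.trait)
    audit.insert(1, "approach", rs.approach)
    audit.to_csv(path, sep="\t", index=False)
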