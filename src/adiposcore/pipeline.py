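"""End-to-end orchestration: simulate -> QC -> internal GWAS -> risk sets ->
PRS -> associations -> clustering, with serialized intermediates, a run
manifest and fixed-seed reproducibility.

Every stage writes plain-text outputs (VCF / TSV) into the run directory
and can be re-run from its predecessor's files, so intermediate counts are
auditable.
"""

from __future__ import annotations

import configparser
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .association_stats import (ADIPOSITY_TRAITS, ancestry_pcs, association_table,
                                fit_prs_association, inverse_normal_transform,
                                spearman_matrix)
from .effect_clustering import build_effect_matrix, render_heatmap, ward_linkage
from .internal_gwas import TRAIT_PLAN, run_internal_gwas, results_table
from .io_and_qc import (QcConfig, apply_sample_exclusions, apply_variant_qc,
                        read_dosages, write_vcf)
from .prs_engine import compute_prs
from .risk_sets import TRAITS, build_risk_set, read_catalog, write_catalog, write_risk_set
from .synthetic_cohort import (DEFAULT_N_MISSING, DEFAULT_N_PREGNANT,
                               default_architecture, flag_exclusions,
                               simulate_catalog, simulate_genotypes,
                               simulate_phenotypes)

log = logging.getLogger(__name__)

STAGES = ("simulate", "qc", "gwas", "risk_sets", "prs", "associate", "cluster")

_QC_KEYS = {f.name for f in QcConfig.__dataclass_fields__.values()}
_RUN_KEYS = {"approaches", "model", "bmi_adjust", "outdir", "seed", "cluster_columns"}
_SIM_KEYS = {"n_samples", "n_families", "family_sd", "n_false", "n_pregnant",
             "n_missing"}


class ConfigError(ValueError):
    pass


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    version: str
    stage_counts: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)

    def save(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2, sort_keys=True)
            fh.write("\n")


def validate_config(config_path: str | None) -> dict:
    """Parse and normalize a flat key=value config with [qc], [simulate] and
    [run] sections; all omitted thresholds fall back to QcConfig defaults.
    Unknown keys and out-of-range thresholds are collected into one error.
    """
    cfg = {
        "qc": {f: getattr(QcConfig(), f) for f in _QC_KEYS},
        "simulate": {"n_samples": 2554, "n_families": 600, "family_sd": 0.25,
                     "n_false": 12, "n_pregnant": DEFAULT_N_PREGNANT,
                     "n_missing": DEFAULT_N_MISSING},
        "run": {"approaches": [1, 2, 3], "model": "ols", "bmi_adjust": "both",
                "outdir": "adiposcore_run", "seed": 0, "cluster_columns": True},
    }
    if config_path is None:
        cfg["qc"] = QcConfig()
        return cfg
    parser = configparser.ConfigParser()
    read = parser.read(config_path)
    if not read:
        raise ConfigError(f"config file {config_path} not found or unreadable")
    errors: list[str] = []
    for section in parser.sections():
        if section not in cfg:
            errors.append(f"unknown section [{section}]")
            continue
        allowed = {"qc": _QC_KEYS, "simulate": _SIM_KEYS, "run": _RUN_KEYS}[section]
        for key, raw in parser.items(section):
            if key not in allowed:
                errors.append(f"unknown key {key!r} in [{section}]")
                continue
            try:
                if key == "approaches":
                    val = [int(x) for x in raw.split(",")]
                    if not set(val) <= {1, 2, 3}:
                        raise ValueError(raw)
                elif key in ("model", "bmi_adjust", "outdir"):
                    val = raw
                elif key == "cluster_columns":
                    val = raw.lower() in ("1", "true", "yes", "on")
                elif key in ("n_samples", "n_families", "n_false", "n_pcs",
                             "seed", "n_pregnant", "n_missing"):
                    val = int(raw)
                else:
                    val = float(raw)
            except ValueError:
                errors.append(f"cannot parse {section}.{key}={raw!r}")
                continue
            cfg[section][key] = val
    if cfg["run"]["model"] not in ("ols", "mixed"):
        errors.append(f"run.model must be ols|mixed, got {cfg['run']['model']!r}")
    if cfg["run"]["bmi_adjust"] not in ("on", "off", "both"):
        errors.append("run.bmi_adjust must be on|off|both")
    try:
        cfg["qc"] = QcConfig(**cfg["qc"])
    except ValueError as exc:
        errors.append(str(exc))
    if errors:
        raise ConfigError("; ".join(errors))
    return cfg


def _hash_config(cfg: dict) -> str:
    flat = {k: (dict(v.__dict__) if isinstance(v, QcConfig) else dict(v))
            for k, v in cfg.items()}
    flat["run"].pop("outdir", None)  # a location, not an analysis input
    return hashlib.sha256(
        json.dumps(flat, sort_keys=True, default=str).encode()).hexdigest()[:16]


def run_pipeline(config_path: str | None = None, seed: int | None = None,
                 outdir: str | None = None, stages=STAGES) -> RunManifest:
    """Execute the pipeline stages in order, writing every intermediate and
    a JSON manifest into ``outdir``. Identical config + seed reproduce
    byte-identical outputs."""
    cfg = validate_config(config_path)
    if seed is not None:
        cfg["run"]["seed"] = int(seed)
    if outdir is not None:
        cfg["run"]["outdir"] = outdir
    out = cfg["run"]["outdir"]
    os.makedirs(out, exist_ok=True)
    qc: QcConfig = cfg["qc"]
    seed = int(cfg["run"]["seed"])
    man = RunManifest(config_hash=_hash_config(cfg), seed=seed, version=__version__)

    def p(name: str) -> str:
        return os.path.join(out, name)

    if "simulate" in stages:
        sim = cfg["simulate"]
        spec = default_architecture(n_samples=sim["n_samples"], seed=seed,
                                    n_families=sim["n_families"],
                                    family_sd=sim["family_sd"])
        gm = simulate_genotypes(spec)
        ct = simulate_phenotypes(gm, spec)
        ct = flag_exclusions(ct, sim["n_pregnant"], sim["n_missing"], seed=seed)
        catalog = simulate_catalog(gm, spec, n_false=sim["n_false"], seed=seed)
        write_vcf(gm, p("genotypes.vcf"))
        ct.to_csv(p("cohort.tsv"), sep="\t", index=False)
        write_catalog(catalog, p("catalog.tsv"))
        man.stage_counts["simulate"] = {"samples": gm.n_samples,
                                        "variants": gm.n_variants,
                                        "catalog": len(catalog)}
        man.outputs["genotypes"] = p("genotypes.vcf")
        man.outputs["cohort"] = p("cohort.tsv")
        man.outputs["catalog"] = p("catalog.tsv")

    ct = pd.read_csv(p("cohort.tsv"), sep="\t")
    catalog = read_catalog(p("catalog.tsv"))

    if "qc" in stages:
        gm = read_dosages(p("genotypes.vcf"))
        gm, audit = apply_variant_qc(gm, qc)
        write_vcf(gm, p("genotypes_qc.vcf"))
        audit.to_csv(p("variant_qc_audit.tsv"), sep="\t", index=False)
        analysed = apply_sample_exclusions(ct[ct["visit"] == 2])
        man.stage_counts["qc"] = {"variants_kept": gm.n_variants,
                                  "variants_dropped": len(audit),
                                  "analysed_samples": len(analysed)}
    elif os.path.exists(p("genotypes_qc.vcf")):
        gm = read_dosages(p("genotypes_qc.vcf"))
    else:
        gm = read_dosages(p("genotypes.vcf"))

    pcs = ancestry_pcs(gm, min(qc.n_pcs, gm.n_variants, gm.n_samples))

    gwas_results = []
    if "gwas" in stages:
        for trait in dict.fromkeys(list(TRAITS) + list(ADIPOSITY_TRAITS)):
            gwas_results.extend(run_internal_gwas(gm, ct, trait, qc, pcs=pcs))
        results_table(gwas_results).to_csv(p("internal_gwas.tsv"), sep="\t", index=False)
        man.stage_counts["gwas"] = {"tests": len(gwas_results)}
        man.outputs["internal_gwas"] = p("internal_gwas.tsv")

    risk_sets: dict[tuple[str, int], object] = {}
    if "risk_sets" in stages:
        from .internal_gwas import GwasResult
        if not gwas_results and os.path.exists(p("internal_gwas.tsv")):
            df = pd.read_csv(p("internal_gwas.tsv"), sep="\t")
            gwas_results = [GwasResult(key=r.key, trait=r.trait, beta=r.beta,
                                       se=r.se, p=r.p, n_used=int(r.n),
                                       bmi_adjusted=bool(r.bmi_adjusted))
                            for r in df.itertuples()]
        counts = {}
        for trait in TRAITS:
            for approach in cfg["run"]["approaches"]:
                internal = gwas_results if approach >= 2 else None
                rs = build_risk_set(catalog, internal, approach, gm, qc, trait=trait)
                risk_sets[(trait, approach)] = rs
                write_risk_set(rs, p(f"risk_set_{trait}_a{approach}.tsv"))
                counts[f"{trait}_a{approach}"] = len(rs.entries)
        man.stage_counts["risk_sets"] = counts

    prs_vectors = {}
    if "prs" in stages and risk_sets:
        from .prs_engine import EmptyRiskSetError
        frames = []
        for (trait, approach), rs in risk_sets.items():
            try:
                pv = compute_prs(gm, rs)
            except EmptyRiskSetError:
                log.warning("empty risk set for %s approach %d; PRS skipped",
                            trait, approach)
                continue
            prs_vectors[(trait, approach)] = pv
            frames.append(pv.to_frame())
        pd.concat(frames, ignore_index=True).to_csv(p("prs.tsv"), sep="\t", index=False)
        man.outputs["prs"] = p("prs.tsv")

    if "associate" in stages:
        analysed = apply_sample_exclusions(ct[ct["visit"] == 2])
        analysed = analysed.set_index("sample_id").reindex(gm.sample_ids)
        with np.errstate(divide="ignore", invalid="ignore"):
            vsr = (analysed["VAT"] / analysed["SAT"]).to_numpy(dtype=float)
        vsr[~np.isfinite(vsr)] = np.nan
        outcomes = {"BFpct": analysed["BFpct"].to_numpy(dtype=float),
                    "SAT": analysed["SAT"].to_numpy(dtype=float),
                    "VAT": analysed["VAT"].to_numpy(dtype=float),
                    "VSR": vsr}
        outcomes_z = {k: inverse_normal_transform(v) for k, v in outcomes.items()}
        bmi_z = inverse_normal_transform(analysed["BMI"].to_numpy(dtype=float))
        covs = np.column_stack([
            analysed["age"].to_numpy(dtype=float),
            (analysed["sex"] == "male").astype(float).where(analysed["sex"].notna()),
            pcs])
        fam = analysed["family_id"]
        bmi_modes = {"on": [True], "off": [False],
                     "both": [False, True]}[cfg["run"]["bmi_adjust"]]
        results = []
        for (trait, approach), pv in prs_vectors.items():
            for outcome, yz in outcomes_z.items():
                for adj in bmi_modes:
                    results.append(fit_prs_association(
                        yz, pv.scores, covariates=covs,
                        bmi=bmi_z if adj else None,
                        model=cfg["run"]["model"],
                        family_ids=fam if cfg["run"]["model"] == "mixed" else None,
                        outcome=outcome, prs_trait=trait, approach=approach))
        association_table(results).to_csv(p("associations.tsv"), sep="\t", index=False)
        # PRS validation: each score against its own source phenotype
        validations = []
        for (trait, approach), pv in prs_vectors.items():
            column, _, bmi_adj = TRAIT_PLAN[trait]
            own = inverse_normal_transform(analysed[column].to_numpy(dtype=float))
            validations.append(fit_prs_association(
                own, pv.scores, covariates=covs, bmi=bmi_z if bmi_adj else None,
                model="ols", outcome=trait, prs_trait=trait, approach=approach))
        association_table(validations).to_csv(p("prs_validation.tsv"), sep="\t",
                                              index=False)
        spearman_matrix(analysed.reset_index(),
                        ["BMI", "WC", "HC", "WHR", "BFpct", "SAT", "VAT"]
                        ).to_csv(p("spearman.tsv"), sep="\t")
        man.stage_counts["associate"] = {"models": len(results)}
        man.outputs["associations"] = p("associations.tsv")
        man.outputs["spearman"] = p("spearman.tsv")

    if "cluster" in stages and risk_sets:
        approach = max(a for (_, a) in risk_sets)
        selected = {t: risk_sets[(t, approach)] for t in TRAITS
                    if (t, approach) in risk_sets}
        em = build_effect_matrix(gwas_results, selected)
        if len(em.values) >= 2:
            rows_tree = ward_linkage(em.values.to_numpy(dtype=float))
            cols_tree = (ward_linkage(em.values.to_numpy(dtype=float).T)
                         if cfg["run"]["cluster_columns"] else None)
            render_heatmap(em, rows_tree, cols_tree, p("effect_heatmap.png"),
                           tsv_path=p("effect_matrix_ordered.tsv"))
            man.outputs["effect_matrix"] = p("effect_matrix_ordered.tsv")
        man.stage_counts["cluster"] = {"rows": len(em.values),
                                       "dropped": len(em.audit)}

    man.save(p("manifest.json"))
    return man
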