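"""Per-variant association screen on the inverse-normal scale.

Ordinary least squares of the inverse-normal-transformed phenotype on each
variant's dosage plus covariates (age, sex, optional ancestry PCs; BMI for
the BMI-adjusted girth traits), with a Wald t test. This is the in-cohort
replication screen behind risk-set approaches 2 and 3 and the source of
the per-variant effect sizes used for clustering.

The genome-wide mixed-model (GRM) machinery of large-cohort pipelines is
deliberately not reproduced here: at the scale of a sign-and-significance
replication screen a covariate-adjusted linear model is the fitted model,
and the interface leaves room for a drop-in mixed solver.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_and_qc import GenotypeMatrix, QcConfig


class DegenerateVariantError(ValueError):
    """Constant dosage — no association estimable."""


class RankDeficientError(ValueError):
    """Collinear design matrix (message names the offending columns)."""


@dataclass(frozen=True)
class GwasResult:
    """One variant x trait association on the z-score scale."""

    key: str
    trait: str
    beta: float  # per effect allele
    se: float
    p: float
    n_used: int
    bmi_adjusted: bool = False


#: PRS trait -> (cohort phenotype column, analysis visit, BMI adjusted?).
TRAIT_PLAN = {
    "BMI": ("BMI", 1, False),
    "WCadjBMI": ("WC", 1, True),
    "WHRadjBMI": ("WHR", 2, True),
    "BFpct": ("BFpct", 2, False),
    # outcome adiposity traits, used for per-variant effect matrices
    "SAT": ("SAT", 2, False),
    "VAT": ("VAT", 2, False),
    "VSR": ("VSR", 2, False),
}


def _ols(y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, int]:
    """Closed-form OLS: coefficients, standard errors, two-sided t p-values,
    residual df. Raises on rank deficiency."""
    n, p = X.shape
    if n < p + 1:
        raise ValueError(f"too few complete cases ({n}) for {p} parameters")
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        norms = np.linalg.norm(X, axis=0)
        bad = [str(j) for j in np.where(norms == 0)[0]] or ["(linear dependence)"]
        raise RankDeficientError(f"design rank {rank} < {p}; columns: {','.join(bad)}")
    XtX = X.T @ X
    beta = np.linalg.solve(XtX, X.T @ y)
    resid = y - X @ beta
    df = n - p
    sigma2 = float(resid @ resid) / df
    cov = sigma2 * np.linalg.inv(XtX)
    se = np.sqrt(np.diag(cov))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta / se
    pvals = 2.0 * stats.t.sf(np.abs(t), df=df)
    return beta, se, pvals, df


def assoc_per_variant(dosage: np.ndarray, phenotype_z: np.ndarray,
                      covariates: np.ndarray | None = None,
                      effect_allele_is_alt: bool = True,
                      key: str = "", trait: str = "",
                      bmi_adjusted: bool = False) -> GwasResult:
    """OLS of an inverse-normal phenotype on one variant's dosage plus
    covariates; Wald t test with residual df.

    The slope is oriented to the effect allele: when the effect allele is
    the reference allele the dosage axis is reversed, so beta is negated
    (p unchanged).
    """
    d = np.asarray(dosage, dtype=float)
    y = np.asarray(phenotype_z, dtype=float)
    C = (np.empty((len(y), 0)) if covariates is None
         else np.atleast_2d(np.asarray(covariates, dtype=float)))
    if C.ndim == 2 and C.shape[0] != len(y) and C.shape[1] == len(y):
        C = C.T
    ok = ~(np.isnan(d) | np.isnan(y) | np.isnan(C).any(axis=1))
    d, y, C = d[ok], y[ok], C[ok]
    if d.size and np.ptp(d) == 0:
        raise DegenerateVariantError(f"constant dosage for {key or 'variant'}")
    X = np.column_stack([np.ones_like(d), d, C])
    beta, se, pvals, _ = _ols(y, X)
    b = float(beta[1])
    if not effect_allele_is_alt:
        b = -b
    return GwasResult(key=key, trait=trait, beta=b, se=float(se[1]),
                      p=float(pvals[1]), n_used=int(d.size),
                      bmi_adjusted=bmi_adjusted)


def run_internal_gwas(gm: GenotypeMatrix, ct: pd.DataFrame, trait: str,
                      cfg: QcConfig | None = None,
                      pcs: np.ndarray | None = None,
                      visit: int | None = None) -> list[GwasResult]:
    """Per-variant association of one trait against every variant.

    Applies the trait's analysis-visit selection (anthropometrics at
    visit 1 to maximize sample size, CT/bioimpedance traits at visit 2),
    sample exclusions, the inverse-normal transform, BMI adjustment for the
    BMI-adjusted girth traits, and per-variant mean imputation of missing
    dosages. ``pcs`` rows must align with ``gm.sample_ids``.
    """
    from .association_stats import inverse_normal_transform
    from .io_and_qc import apply_sample_exclusions

    cfg = cfg or QcConfig()
    if trait not in TRAIT_PLAN:
        raise KeyError(f"unknown trait {trait!r}")
    column, default_visit, bmi_adj = TRAIT_PLAN[trait]
    visit = default_visit if visit is None else visit

    sub = ct[ct["visit"] == visit]
    sub = apply_sample_exclusions(sub)
    sub = sub.set_index("sample_id").reindex(gm.sample_ids)
    if column == "VSR":
        with np.errstate(divide="ignore", invalid="ignore"):
            raw = (sub["VAT"] / sub["SAT"]).to_numpy(dtype=float)
        raw[~np.isfinite(raw)] = np.nan
    else:
        if column not in sub.columns:
            raise KeyError(f"trait column {column!r} missing from cohort table")
        raw = sub[column].to_numpy(dtype=float)
    y = inverse_normal_transform(raw)

    cov_cols = [
        (sub["age"].to_numpy(dtype=float)),
        (sub["sex"] == "male").astype(float).where(sub["sex"].notna()).to_numpy(dtype=float),
    ]
    if bmi_adj:
        cov_cols.append(inverse_normal_transform(sub["BMI"].to_numpy(dtype=float)))
    C = np.column_stack(cov_cols)
    if pcs is not None and pcs.shape[1] > 0:
        C = np.column_stack([C, pcs])

    results = []
    for j, rec in enumerate(gm.variants):
        d = gm.dosages[:, j].copy()
        miss = np.isnan(d)
        if miss.all():
            continue
        if miss.any():
            d[miss] = d[~miss].mean()
        try:
            res = assoc_per_variant(d, y, C, effect_allele_is_alt=True,
                                    key=rec.key, trait=trait, bmi_adjusted=bmi_adj)
        except DegenerateVariantError:
            continue
        results.append(res)
    return results


def results_table(results: list[GwasResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"key": r.key, "trait": r.trait, "beta": r.beta, "se": r.se,
          "p": r.p, "n": r.n_used, "bmi_adjusted": r.bmi_adjusted}
         for r in results],
        columns=["key", "trait", "beta", "se", "p", "n", "bmi_adjusted"])
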