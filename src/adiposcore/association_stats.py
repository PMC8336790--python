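"""PRS-phenotype association analytics.

Inverse-normal (Blom) transformation, ancestry principal components from
the standardized dosage matrix, multivariable linear (and random-intercept
mixed) models of each adiposity outcome on a raw-count PRS with age, sex,
top ancestry PCs and optionally BMI as covariates, incremental variance
explained, and the Spearman phenotype correlation matrix.

Effect sizes are reported as ``beta_x100`` = 100 x the raw slope, i.e. the
percent change in the outcome z-score per additional trait-increasing
allele.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

log = logging.getLogger(__name__)

ADIPOSITY_TRAITS = ("BFpct", "SAT", "VAT", "VSR")


class DegenerateInputError(ValueError):
    pass


@dataclass(frozen=True)
class AssociationResult:
    """One PRS x outcome x adjustment model fit."""

    outcome: str
    prs_trait: str
    approach: int
    beta_x100: float  # % change in outcome z-score per risk allele
    ci95: tuple[float, float]
    p: float
    model: str  # "ols" | "mixed"
    bmi_adjusted: bool
    r2_incremental: float  # R^2(full) - R^2(covariates only); nan for mixed
    n_used: int

    def __post_init__(self) -> None:
        lo, hi = self.ci95
        if not (lo <= self.beta_x100 <= hi):
            raise ValueError("ci95 does not bracket beta_x100")


def inverse_normal_transform(values) -> np.ndarray:
    """Rank-based inverse-normal transform with the Blom offset:
    ``Phi^-1((r - 3/8) / (n + 1/4))`` over non-missing entries, average
    ranks for ties; missing values stay missing."""
    x = np.asarray(values, dtype=float)
    out = np.full(x.shape, np.nan)
    ok = ~np.isnan(x)
    n = int(ok.sum())
    if n < 2:
        raise DegenerateInputError("need at least 2 non-missing values")
    if np.ptp(x[ok]) == 0:
        raise DegenerateInputError("all non-missing values identical")
    ranks = stats.rankdata(x[ok], method="average")
    out[ok] = stats.norm.ppf((ranks - 0.375) / (n + 0.25))
    return out


def ancestry_pcs(gm, k: int) -> np.ndarray:
    """Top-k principal component scores of the variant-standardized dosage
    matrix (centre by 2f, scale by sqrt(2f(1-f))); monomorphic variants are
    excluded, missing dosages contribute 0 after centring. Component signs
    are fixed so each PC's largest-magnitude sample score is positive."""
    D = gm.dosages
    n, m = D.shape
    if k < 0 or k > min(n, m):
        raise ValueError(f"k={k} outside [0, {min(n, m)}]")
    if k == 0:
        return np.empty((n, 0))
    with np.errstate(invalid="ignore"):
        f = np.nanmean(D, axis=0) / 2.0
    poly = (f > 0) & (f < 1)
    X = (D[:, poly] - 2 * f[poly]) / np.sqrt(2 * f[poly] * (1 - f[poly]))
    X = np.nan_to_num(X, nan=0.0)
    U, S, _ = np.linalg.svd(X, full_matrices=False)
    scores = U[:, :k] * S[:k]
    for j in range(scores.shape[1]):
        i = int(np.argmax(np.abs(scores[:, j])))
        if scores[i, j] < 0:
            scores[:, j] = -scores[:, j]
    return scores


def _design(prs, covariates, bmi):
    parts = [np.ones(len(prs)), np.asarray(prs, dtype=float)]
    names = ["const", "prs"]
    if covariates is not None:
        C = np.atleast_2d(np.asarray(covariates, dtype=float))
        if C.shape[0] != len(prs) and C.shape[1] == len(prs):
            C = C.T
        for j in range(C.shape[1]):
            parts.append(C[:, j])
            names.append(f"cov{j}")
    if bmi is not None:
        parts.append(np.asarray(bmi, dtype=float))
        names.append("bmi")
    return np.column_stack(parts), names


def fit_prs_association(outcome_z, prs, covariates=None, bmi=None,
                        model: str = "ols", family_ids=None,
                        outcome: str = "", prs_trait: str = "",
                        approach: int = 1) -> AssociationResult:
    """Regress an inverse-normal outcome on a raw-count PRS plus covariates.

    ``beta_x100`` is 100x the fitted slope; the 95% CI comes from t
    quantiles (normal quantiles for the mixed model);
    ``r2_incremental`` is R^2 of the full OLS model minus R^2 of the
    covariates-only model. ``model="mixed"`` adds a family random intercept
    (REML) and requires ``family_ids``.
    """
    import statsmodels.api as sm

    y = np.asarray(outcome_z, dtype=float)
    s = np.asarray(prs, dtype=float)
    X, names = _design(s, covariates, bmi)
    ok = ~(np.isnan(y) | np.isnan(X).any(axis=1))
    if family_ids is not None:
        fam = pd.Series(family_ids).to_numpy()
        ok &= pd.notna(fam)
    y, X = y[ok], X[ok]
    n = int(ok.sum())
    if n <= X.shape[1]:
        raise ValueError(f"complete-case n={n} does not exceed {X.shape[1]} parameters")
    if np.ptp(X[:, 1]) == 0:
        raise DegenerateInputError("constant PRS")

    if model == "ols":
        fit = sm.OLS(y, X).fit()
        beta, se, p = fit.params[1], fit.bse[1], fit.pvalues[1]
        tq = stats.t.ppf(0.975, df=fit.df_resid)
        cov_only = sm.OLS(y, np.delete(X, 1, axis=1)).fit()
        r2_inc = max(0.0, float(fit.rsquared - cov_only.rsquared))
    elif model == "mixed":
        if family_ids is None:
            raise ValueError("mixed model requires family_ids")
        res = mixed_random_intercept(y, X, fam[ok])
        beta, se = res["beta"][1], res["se"][1]
        p = 2.0 * stats.norm.sf(abs(beta / se))
        tq = stats.norm.ppf(0.975)
        r2_inc = float("nan")
    else:
        raise ValueError(f"unknown model {model!r}")

    b100 = 100.0 * float(beta)
    ci = (b100 - 100.0 * tq * float(se), b100 + 100.0 * tq * float(se))
    return AssociationResult(outcome=outcome, prs_trait=prs_trait,
                             approach=approach, beta_x100=b100, ci95=ci,
                             p=float(p), model=model,
                             bmi_adjusted=bmi is not None,
                             r2_incremental=r2_inc, n_used=n)


def mixed_random_intercept(y, X, family_ids, lam: float | None = None) -> dict:
    """Linear mixed model with one random intercept per family, fitted by
    REML profiling of the single variance ratio lambda = sigma^2_family /
    sigma^2_resid.

    For fixed lambda the marginal covariance is block-diagonal, each block
    ``sigma^2_e (I + lambda J)``, inverted in closed form, so the profile
    criterion is one-dimensional and optimized by bounded scalar search on
    log(lambda), with the boundary lambda = 0 checked explicitly. Passing
    ``lam`` skips estimation and fits GLS at that fixed ratio.

    Returns beta, se, sigma2_resid, sigma2_family, lambda and the REML
    criterion value.
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    fam = pd.Series(family_ids).to_numpy()
    n, p = X.shape
    codes, _ = pd.factorize(fam)
    if codes.max() < 1:
        raise ValueError("need at least 2 families")
    groups = [np.flatnonzero(codes == g) for g in range(codes.max() + 1)]

    # per-family sufficient pieces
    pre = []
    for idx in groups:
        Xf, yf = X[idx], y[idx]
        ones = np.ones(len(idx))
        pre.append((len(idx), Xf.T @ Xf, Xf.T @ yf, float(yf @ yf),
                    Xf.T @ ones, float(yf @ ones)))

    def gls(lmb: float):
        A = np.zeros((p, p))
        b = np.zeros(p)
        yy = 0.0
        logdet = 0.0
        for m, XtX, Xty, yty, Xt1, yt1 in pre:
            w = lmb / (1.0 + lmb * m)
            A += XtX - w * np.outer(Xt1, Xt1)
            b += Xty - w * Xt1 * yt1
            yy += yty - w * yt1 * yt1
            logdet += np.log1p(lmb * m)
        beta = np.linalg.solve(A, b)
        rss = yy - float(b @ beta)
        return A, beta, max(rss, 1e-300), logdet

    def neg_reml(log_lmb: float) -> float:
        lmb = np.exp(log_lmb)
        A, _, rss, logdet = gls(lmb)
        sign, logdetA = np.linalg.slogdet(A)
        return 0.5 * (logdet + (n - p) * np.log(rss) + logdetA)

    if lam is None:
        opt = optimize.minimize_scalar(neg_reml, bounds=(-14.0, 8.0),
                                       method="bounded",
                                       options={"xatol": 1e-12})
        if not opt.success:
            raise RuntimeError(
                f"REML profiling failed to converge on log-lambda in [-14, 8]: {opt.message}")
        at_zero = 0.5 * ((n - p) * np.log(gls(0.0)[2])
                         + np.linalg.slogdet(gls(0.0)[0])[1])
        if at_zero <= opt.fun + 1e-10:
            lam_hat, crit = 0.0, at_zero
        else:
            lam_hat, crit = float(np.exp(opt.x)), float(opt.fun)
    else:
        if lam < 0:
            raise ValueError("lambda must be >= 0")
        lam_hat = float(lam)
        crit = float("nan")

    A, beta, rss, _ = gls(lam_hat)
    sigma2_e = rss / (n - p)
    cov = sigma2_e * np.linalg.inv(A)
    return {
        "beta": beta, "se": np.sqrt(np.diag(cov)),
        "sigma2_resid": sigma2_e, "sigma2_family": lam_hat * sigma2_e,
        "lambda": lam_hat, "reml_criterion": crit,
    }


def spearman_matrix(ct: pd.DataFrame, traits: list[str]) -> pd.DataFrame:
    """Pairwise-complete Spearman correlations among phenotype columns;
    diagonal exactly 1; cells with fewer than 3 complete pairs are missing
    (with a warning)."""
    sub = ct[list(traits)].astype(float)
    out = sub.corr(method="spearman", min_periods=3)
    np.fill_diagonal(out.values, 1.0)
    for i, a in enumerate(traits):
        for b in traits[i + 1:]:
            if pd.isna(out.loc[a, b]):
                log.warning("fewer than 3 complete pairs for (%s, %s)", a, b)
    return out


def association_table(results: list[AssociationResult]) -> pd.DataFrame:
    rows = [{"outcome": r.outcome, "prs_trait": r.prs_trait, "approach": r.approach,
             "beta_x100": r.beta_x100, "ci_lo": r.ci95[0], "ci_hi": r.ci95[1],
             "p": r.p, "model": r.model, "bmi_adjusted": r.bmi_adjusted,
             "r2_incremental": r.r2_incremental, "n": r.n_used}
            for r in results]
    return pd.DataFrame(rows, columns=["outcome", "prs_trait", "approach",
                                       "beta_x100", "ci_lo", "ci_hi", "p",
                                       "model", "bmi_adjusted", "r2_incremental", "n"])
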