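"""Case-control association: CMH across strata, IRLS logistic, scan-level QC.

Population structure is handled either by Cochran-Mantel-Haenszel analysis on
per-stratum allele-count tables (cluster labels as strata) or by logistic
regression with eigenvector covariates. The genomic inflation factor lambda
(median association chi-square over its 1-df null median) summarizes residual
stratification.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit
from sklearn.base import BaseEstimator
from statsmodels.stats.contingency_tables import StratifiedTable

log = logging.getLogger(__name__)

GENOME_WIDE_P = 5e-8
CHI2_1DF_MEDIAN = float(stats.chi2.ppf(0.5, 1))  # 0.4549...

GENOTYPE_CODINGS = ("additive", "dominant", "recessive", "carrier")


class UntestableError(ValueError):
    """No informative stratum / zero-variance predictor."""


@dataclass
class AssociationResult:
    """Effect of one variant: log OR with Wald SE, OR with 95% CI, p-value."""

    beta: float
    se: float
    p: float
    test: str                  # {"cmh", "logistic", "conditional"}
    n_eff: int = 0
    flag: str | None = None    # e.g. separation / collinearity / monomorphic note

    @property
    def or_(self) -> float:
        return math.exp(self.beta)

    @property
    def ci95(self) -> tuple:
        return (math.exp(self.beta - 1.96 * self.se),
                math.exp(self.beta + 1.96 * self.se))

    @property
    def chisq(self) -> float:
        return (self.beta / self.se) ** 2 if self.se > 0 else float("nan")


def cmh_allelic_test(tables) -> AssociationResult:
    """Mantel-Haenszel common OR over per-stratum 2x2 allele-count tables.

    ``tables``: iterable of [[case_risk, case_other], [control_risk,
    control_other]] integer tables. Strata with a zero margin are dropped with
    a warning; SE is Robins-Breslow-Greenland; p from the 1-df CMH chi-square
    without continuity correction.
    """
    kept = []
    for i, t in enumerate(tables):
        t = np.asarray(t, dtype=float)
        if t.shape != (2, 2) or np.any(t < 0):
            raise ValueError(f"stratum {i} is not a non-negative 2x2 table")
        if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
            log.warning("dropping stratum %d with zero margin: %s", i, t.tolist())
            continue
        kept.append(t)
    if not kept:
        raise UntestableError("all strata degenerate (zero margins)")
    st = StratifiedTable(np.dstack(kept))
    beta = float(np.log(st.oddsratio_pooled))
    se = float(st.logodds_pooled_se)
    p = float(st.test_null_odds(correction=False).pvalue)
    return AssociationResult(beta=beta, se=se, p=p, test="cmh",
                             n_eff=int(sum(t.sum() for t in kept)))


class LogisticRegressionIRLS(BaseEstimator):
    """Maximum-likelihood logistic regression via iteratively reweighted LS.

    Statistical (not predictive) flavour: reports Wald SEs from the inverse
    Fisher information and the fitted log-likelihood for downstream BIC and
    pseudo-r2 bookkeeping. Suspected complete separation (any |beta| above
    ``beta_cap``) or non-convergence is flagged, never silent.

    Attributes after ``fit``: ``coef_`` (intercept first when
    ``add_intercept``), ``se_``, ``cov_``, ``loglik_``, ``n_iter_``,
    ``converged_``, ``separation_``, ``pvalues_``.
    """

    def __init__(self, add_intercept=True, max_iter=100, tol=1e-10, beta_cap=15.0):
        self.add_intercept = add_intercept
        self.max_iter = max_iter
        self.tol = tol
        self.beta_cap = beta_cap

    def _design(self, X):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if self.add_intercept:
            X = np.column_stack([np.ones(X.shape[0]), X])
        return X

    def fit(self, X, y):
        y = np.asarray(y, dtype=float).ravel()
        X = self._design(X)
        n, k = X.shape
        if n <= k:
            raise ValueError(f"n={n} must exceed number of columns k={k}")
        if np.linalg.matrix_rank(X) < k:
            raise np.linalg.LinAlgError("design matrix is rank deficient")
        beta = np.zeros(k)
        converged = False
        for it in range(1, self.max_iter + 1):
            eta = np.clip(X @ beta, -30, 30)
            mu = expit(eta)
            w = mu * (1 - mu)
            info = X.T @ (X * w[:, None])
            grad = X.T @ (y - mu)
            try:
                step = np.linalg.solve(info, grad)
            except np.linalg.LinAlgError:
                break
            beta = beta + step
            if np.max(np.abs(step)) < self.tol:
                converged = True
                break
        eta = np.clip(X @ beta, -30, 30)
        mu = expit(eta)
        info = X.T @ (X * (mu * (1 - mu))[:, None])
        self.cov_ = np.linalg.pinv(info)
        self.coef_ = beta
        self.se_ = np.sqrt(np.maximum(np.diag(self.cov_), 0.0))
        self.loglik_ = float(np.sum(y * eta - np.log1p(np.exp(eta))))
        self.n_iter_ = it
        self.converged_ = converged
        self.separation_ = bool(np.any(np.abs(beta) > self.beta_cap))
        with np.errstate(divide="ignore", invalid="ignore"):
            z = np.where(self.se_ > 0, beta / self.se_, np.inf * np.sign(beta))
        self.pvalues_ = 2 * stats.norm.sf(np.abs(z))
        self.n_ = n
        self.k_ = k
        return self

    def predict_proba_1d(self, X):
        return expit(self._design(X) @ self.coef_)


def fit_logistic(y, X, add_intercept: bool = True) -> LogisticRegressionIRLS:
    """IRLS logistic fit; returns the fitted estimator (coefs, SEs, loglik)."""
    return LogisticRegressionIRLS(add_intercept=add_intercept).fit(X, y)


def apply_coding(g: np.ndarray, coding: str) -> np.ndarray:
    """Genotype coding: additive 0/1/2, dominant & carrier 0/1/1, recessive 0/0/1."""
    g = np.asarray(g, dtype=float)
    if coding == "additive":
        return g
    if coding in ("dominant", "carrier"):
        return (g >= 1).astype(float)
    if coding == "recessive":
        return (g >= 2).astype(float)
    raise ValueError(f"unknown coding {coding!r}; expected one of {GENOTYPE_CODINGS}")


def genomic_inflation(chisq) -> float:
    """lambda = median(chi-square) / median of the 1-df chi-square null."""
    arr = np.asarray(chisq, dtype=float)
    arr = arr[np.isfinite(arr)]
    if arr.size == 0:
        raise ValueError("no finite chi-square statistics")
    return float(np.median(arr) / CHI2_1DF_MEDIAN)


@dataclass
class ScanTable:
    """Per-variant association results plus scan-level QC."""

    table: pd.DataFrame
    lambda_: float
    gw_threshold: float = GENOME_WIDE_P
    results: dict = field(default_factory=dict)   # variant -> AssociationResult


def _allele_tables(g, y, strata):
    tables = []
    for s in np.unique(strata):
        m = strata == s
        case, ctrl = m & (y == 1), m & (y == 0)
        a = g[case].sum()
        b = 2 * case.sum() - a
        c = g[ctrl].sum()
        d = 2 * ctrl.sum() - c
        tables.append([[a, b], [c, d]])
    return tables


def association_scan(y, genotypes: pd.DataFrame, *, strata=None, covariates=None,
                     coding: str = "additive", x_variants=(), sex=None,
                     male_x_doubling: bool = False,
                     gw_threshold: float = GENOME_WIDE_P) -> ScanTable:
    """Per-variant case-control scan.

    Uses CMH on per-stratum allele tables when ``strata`` are given and there
    are no covariates (additive/allelic analysis); otherwise logistic
    regression of the coded genotype plus covariates. With
    ``male_x_doubling``, male genotypes at X-flagged variants enter doubled
    (0/2), i.e. one male risk allele counts as two female ones under complete
    X-inactivation.
    """
    y = np.asarray(y, dtype=float).ravel()
    if coding not in GENOTYPE_CODINGS:
        raise ValueError(f"unknown coding {coding!r}")
    use_cmh = strata is not None and covariates is None and coding == "additive"
    strata_arr = np.asarray(strata) if strata is not None else None
    cov = np.atleast_2d(np.asarray(covariates, float)) if covariates is not None else None
    if cov is not None and cov.shape[0] != y.size:
        cov = cov.T
    male = np.asarray(sex) == "M" if sex is not None else np.zeros(y.size, bool)

    rows, results = [], {}
    for name in genotypes.columns:
        g = np.asarray(genotypes[name], dtype=float)
        if male_x_doubling and name in set(x_variants):
            g = np.where(male, 2 * np.minimum(g, 1), g)
        if np.nanstd(g) == 0:
            res = AssociationResult(beta=np.nan, se=np.nan, p=np.nan, test="none",
                                    flag="monomorphic")
        elif use_cmh:
            try:
                res = cmh_allelic_test(_allele_tables(g, y, strata_arr))
            except UntestableError as err:
                res = AssociationResult(np.nan, np.nan, np.nan, "cmh", flag=str(err))
        else:
            x = apply_coding(g, coding)[:, None]
            design = x if cov is None else np.column_stack([x, cov])
            fit = LogisticRegressionIRLS().fit(design, y)
            res = AssociationResult(
                beta=float(fit.coef_[1]), se=float(fit.se_[1]),
                p=float(fit.pvalues_[1]), test="logistic", n_eff=int(y.size),
                flag="separation" if fit.separation_
                else (None if fit.converged_ else "non-convergence"),
            )
        results[name] = res
        rows.append({
            "variant": name, "beta": res.beta, "se": res.se, "or": np.exp(res.beta),
            "ci_lo": res.ci95[0] if np.isfinite(res.se) else np.nan,
            "ci_hi": res.ci95[1] if np.isfinite(res.se) else np.nan,
            "p": res.p, "test": res.test, "chisq": res.chisq,
            "genome_wide": bool(res.p < gw_threshold) if np.isfinite(res.p) else False,
            "flag": res.flag,
        })
    df = pd.DataFrame(rows)
    chisq = df["chisq"].to_numpy()
    lam = genomic_inflation(chisq) if np.isfinite(chisq).any() else np.nan
    return ScanTable(table=df, lambda_=lam, gw_threshold=gw_threshold, results=results)
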