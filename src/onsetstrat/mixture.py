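"""Finite normal-mixture decomposition of disease onset ages.

Fits K-component univariate Gaussian mixtures by EM with multiple restarts,
selects K by BIC (k = 3K - 1 free parameters), and assigns cases to the early
or late subgroup when the component posterior exceeds a threshold (default
0.8); cases below the threshold remain unassigned.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from sklearn.base import BaseEstimator, DensityMixin

from ._utils import as_1d_float

_LOG2PI = np.log(2.0 * np.pi)


class DegenerateDataError(ValueError):
    """Too few or constant ages for the requested component count."""


def _component_logpdf(x, weights, means, sds):
    z = (x[:, None] - means[None, :]) / sds[None, :]
    return np.log(weights)[None, :] - np.log(sds)[None, :] - 0.5 * (_LOG2PI + z * z)


def mixture_loglik(x, weights, means, sds) -> float:
    """Log-likelihood of a 1-D normal mixture at fixed parameters."""
    return float(logsumexp(_component_logpdf(
        as_1d_float(x), np.asarray(weights, float), np.asarray(means, float),
        np.asarray(sds, float)), axis=1).sum())


class GaussianMixture1D(DensityMixin, BaseEstimator):
    """Univariate Gaussian mixture fitted by EM with restarts.

    Parameters
    ----------
    n_components : int or None
        Number of components. ``None`` selects K in 1..k_max by BIC
        (ties broken toward smaller K).
    k_max : int
        Largest K tried when selecting (default 7).
    n_init : int
        EM restarts per K: one deterministic quantile-split initialization
        plus ``n_init - 1`` random ones.
    tol : float
        Relative log-likelihood convergence tolerance.
    sd_floor : float
        Lower bound on component SDs (years); prevents variance collapse.
    random_state : int or None
        Seed for the random restarts.

    Attributes (after ``fit``)
    --------------------------
    weights_, means_, sds_ : component parameters, sorted by ascending mean
    loglik_, bic_, n_components_, n_ : fit summary; BIC = -2 LL + (3K-1) ln n
    bic_trace_ : dict mapping each tried K to its BIC (or "skipped: ..." note)
    loglik_path_ : per-iteration log-likelihoods of the winning EM run
    """

    def __init__(self, n_components=2, k_max=7, n_init=50, tol=1e-7,
                 max_iter=300, sd_floor=0.1, random_state=None):
        self.n_components = n_components
        self.k_max = k_max
        self.n_init = n_init
        self.tol = tol
        self.max_iter = max_iter
        self.sd_floor = sd_floor
        self.random_state = random_state

    # -- EM internals -----------------------------------------------------

    def _em_run(self, x, weights, means, sds):
        n = x.size
        path = []
        ll = -np.inf
        for _ in range(self.max_iter):
            logp = _component_logpdf(x, weights, means, sds)
            norm = logsumexp(logp, axis=1)
            ll_new = float(norm.sum())
            path.append(ll_new)
            resp = np.exp(logp - norm[:, None])
            nk = np.maximum(resp.sum(axis=0), 1e-300)
            weights = nk / n
            means = (resp * x[:, None]).sum(axis=0) / nk
            var = (resp * (x[:, None] - means[None, :]) ** 2).sum(axis=0) / nk
            sds = np.sqrt(np.maximum(var, self.sd_floor ** 2))
            if np.isfinite(ll) and ll_new - ll <= self.tol * abs(ll):
                break
            ll = ll_new
        ll_final = mixture_loglik(x, weights, means, sds)
        path.append(ll_final)
        return ll_final, weights, means, sds, path

    def _fit_k(self, x, k, rng):
        n = x.size
        if n < 5 * k:
            raise DegenerateDataError(f"n={n} < 5*K for K={k}")
        if k > 1 and np.ptp(x) == 0:
            raise DegenerateDataError("all ages identical with K > 1")
        pooled_sd = max(float(x.std()), self.sd_floor)
        inits = []
        chunks = np.array_split(np.sort(x), k)
        inits.append(np.array([c.mean() for c in chunks]))
        uniq = np.unique(x)
        for _ in range(max(self.n_init - 1, 0)):
            if uniq.size >= k:
                inits.append(rng.choice(uniq, size=k, replace=False))
            else:
                inits.append(x.mean() + pooled_sd * rng.standard_normal(k))
        best = None
        for mu0 in inits:
            res = self._em_run(x, np.full(k, 1.0 / k), np.asarray(mu0, float),
                               np.full(k, pooled_sd))
            if best is None or res[0] > best[0]:
                best = res
        ll, weights, means, sds, path = best
        order = np.argsort(means)
        return ll, weights[order], means[order], sds[order], path

    # -- sklearn surface --------------------------------------------------

    def fit(self, X, y=None):
        x = as_1d_float(X, "ages")
        rng = np.random.default_rng(self.random_state)
        n = x.size

        if self.n_components is None:
            trace = {}
            best = None
            for k in range(1, self.k_max + 1):
                try:
                    fitk = self._fit_k(x, k, rng)
                except DegenerateDataError as err:
                    trace[k] = f"skipped: {err}"
                    continue
                bic = -2.0 * fitk[0] + (3 * k - 1) * np.log(n)
                trace[k] = bic
                # strict < keeps the smaller K on ties
                if best is None or bic < best[0]:
                    best = (bic, k, fitk)
            if best is None:
                raise DegenerateDataError("no feasible component count")
            _, k, fitk = best
            self.bic_trace_ = trace
        else:
            k = int(self.n_components)
            fitk = self._fit_k(x, k, rng)
            bic = -2.0 * fitk[0] + (3 * k - 1) * np.log(n)
            self.bic_trace_ = {k: bic}

        ll, self.weights_, self.means_, self.sds_, self.loglik_path_ = fitk
        self.n_components_ = k
        self.loglik_ = ll
        self.n_ = n
        self.bic_ = -2.0 * ll + (3 * k - 1) * np.log(n)
        return self

    def predict_proba(self, X):
        """Posterior component membership for each age."""
        x = as_1d_float(X, "ages")
        logp = _component_logpdf(x, self.weights_, self.means_, self.sds_)
        return np.exp(logp - logsumexp(logp, axis=1)[:, None])

    def score(self, X, y=None):
        x = as_1d_float(X, "ages")
        return mixture_loglik(x, self.weights_, self.means_, self.sds_) / x.size


@dataclass
class SubgroupAssignment:
    """Per-case posteriors and early/late/unassigned labels."""

    assignments: pd.DataFrame          # columns: age, p_early, p_late, label
    threshold: float
    boundaries: dict = field(default_factory=dict)  # label -> (lo, hi) integer ages

    @property
    def labels(self) -> pd.Series:
        return self.assignments["label"]


def fit_gaussian_mixture(ages, k: int, restarts: int = 50, tol: float = 1e-7,
                         seed=None) -> GaussianMixture1D:
    """EM fit with a fixed component count; best of ``restarts`` initializations."""
    return GaussianMixture1D(n_components=k, n_init=restarts, tol=tol,
                             random_state=seed).fit(ages)


def select_components(ages, k_max: int = 7, restarts: int = 50, tol: float = 1e-7,
                      seed=None) -> GaussianMixture1D:
    """Fit K = 1..k_max and return the BIC-minimizing mixture (full trace kept)."""
    return GaussianMixture1D(n_components=None, k_max=k_max, n_init=restarts,
                             tol=tol, random_state=seed).fit(ages)


def classify_subgroups(fit: GaussianMixture1D, ages, threshold: float = 0.8,
                       max_age: int = 120) -> SubgroupAssignment:
    """Label cases early/late when the component posterior exceeds ``threshold``.

    Also reports the contiguous integer age ranges over which each label
    applies under the fitted mixture (the subgroup age boundaries).
    """
    if fit.n_components_ != 2:
        raise ValueError(
            f"subgroup classification needs a 2-component fit, got K={fit.n_components_}"
        )
    x = as_1d_float(ages, "ages")
    post = fit.predict_proba(x)
    best = post.argmax(axis=1)
    label = np.where(post[np.arange(x.size), best] > threshold,
                     np.where(best == 0, "early", "late"), "unassigned")
    df = pd.DataFrame({"age": x, "p_early": post[:, 0], "p_late": post[:, 1],
                       "label": label})

    grid = np.arange(0, max_age + 1, dtype=float)
    gpost = fit.predict_proba(grid)
    boundaries = {}
    gbest = gpost.argmax(axis=1)
    for j, name in enumerate(("early", "late")):
        idx = np.flatnonzero((gpost[:, j] > threshold) & (gbest == j))
        if idx.size:
            boundaries[name] = (int(grid[idx[0]]), int(grid[idx[-1]]))
    return SubgroupAssignment(assignments=df, threshold=threshold,
                              boundaries=boundaries)
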