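"""Variance-explained bookkeeping via McFadden pseudo-r2 differences.

The contribution of a variant set is the difference in McFadden pseudo-r2
between the covariates+variants model and the covariates-only model, both
referenced to the intercept-only null; expressed also as a fraction of an
externally supplied total heritability (which is an input constant here, not
estimated).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .association import LogisticRegressionIRLS


@dataclass
class VarianceContribution:
    label: str
    pseudo_r2_full: float
    pseudo_r2_base: float
    total_h2: float

    @property
    def delta(self) -> float:
        return self.pseudo_r2_full - self.pseudo_r2_base

    @property
    def fraction_of_h2(self) -> float:
        return self.delta / self.total_h2


def mcfadden_r2(loglik_model: float, loglik_null: float) -> float:
    """McFadden pseudo-r2 = 1 - LL_model / LL_null."""
    if loglik_null == 0:
        raise ValueError("degenerate outcome: null log-likelihood is zero")
    return 1.0 - loglik_model / loglik_null


def variant_variance_contribution(y, covariates, variant_sets: dict,
                                  total_h2: float) -> dict:
    """Delta pseudo-r2 (and fraction of total h2) per variant set.

    ``variant_sets``: label -> 1-D or 2-D predictor array; each full model is
    covariates + set, nested above the covariates-only base model on the same
    subjects. Joint sets are reported exactly like singles.
    """
    y = np.asarray(y, float).ravel()
    cov = np.asarray(covariates, float) if covariates is not None else \
        np.empty((y.size, 0))
    if cov.ndim == 1:
        cov = cov[:, None]
    null = LogisticRegressionIRLS().fit(np.empty((y.size, 0)), y)
    base = LogisticRegressionIRLS().fit(cov, y) if cov.shape[1] else null
    r2_base = mcfadden_r2(base.loglik_, null.loglik_)
    out = {}
    for label, preds in variant_sets.items():
        arr = np.asarray(preds, float)
        if arr.ndim == 1:
            arr = arr[:, None]
        if arr.shape[0] != y.size:
            raise ValueError(f"variant set {label!r} is not nested on the same "
                             f"subjects (n={arr.shape[0]} vs {y.size})")
        full = LogisticRegressionIRLS().fit(np.column_stack([cov, arr]), y)
        r2_full = mcfadden_r2(full.loglik_, null.loglik_)
        out[label] = VarianceContribution(
            label=label, pseudo_r2_full=r2_full, pseudo_r2_base=r2_base,
            total_h2=float(total_h2))
    return out
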