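"""Concomitant-autoimmunity contrasts between onset subgroups and case-only
protective-association models."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact

from .association import AssociationResult, LogisticRegressionIRLS


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p ("as or less probable" summation, margins
    fixed). A zero margin makes every table equally (im)probable: p = 1."""
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or np.any(t < 0):
        raise ValueError("need a non-negative 2x2 integer table")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        return 1.0
    return float(fisher_exact(t, alternative="two-sided")[1])


@dataclass
class ComorbidityTable:
    counts: np.ndarray          # rows: subgroups; cols: comorbid yes/no
    row_labels: tuple
    p_fisher: float

    @property
    def frequencies(self) -> np.ndarray:
        return self.counts[:, 0] / self.counts.sum(axis=1)


def subgroup_comorbidity_contrast(subgroup_labels, comorbid,
                                  groups=("early", "late")) -> ComorbidityTable:
    """2x2 contrast of comorbidity frequency between two subgroups."""
    lab = np.asarray(subgroup_labels)
    com = np.asarray(comorbid, int)
    counts = np.array([
        [(com[lab == g] == 1).sum(), (com[lab == g] == 0).sum()] for g in groups
    ])
    return ComorbidityTable(counts=counts, row_labels=tuple(groups),
                            p_fisher=fisher_exact_2x2(counts))


def protective_association(comorbid, classical_carrier, indel_count,
                           covariates=None, collinearity_r: float = 0.999) -> dict:
    """Case-only logistic models of non-primary autoimmunity.

    Fits the classical-allele carrier flag and the indel allele count
    individually and mutually adjusted; ORs below 1 indicate protection. The
    two predictors are expected to be in strong LD; collinearity is flagged.
    """
    y = np.asarray(comorbid, float).ravel()
    cls = np.asarray(classical_carrier, float).ravel()
    ind = np.asarray(indel_count, float).ravel()
    for name, g in (("classical_carrier", cls), ("indel_count", ind)):
        if np.std(g) == 0:
            raise ValueError(f"{name} is monomorphic among cases")
    cov = None if covariates is None else np.asarray(covariates, float)

    def _single(x, label):
        design = x[:, None] if cov is None else np.column_stack([x, cov])
        f = LogisticRegressionIRLS().fit(design, y)
        return AssociationResult(beta=float(f.coef_[1]), se=float(f.se_[1]),
                                 p=float(f.pvalues_[1]), test="logistic",
                                 n_eff=int(y.size),
                                 flag="separation" if f.separation_ else None)

    out = {"classical": _single(cls, "classical"), "indel": _single(ind, "indel")}
    r = np.corrcoef(cls, ind)[0, 1]
    if abs(r) > collinearity_r:
        out["joint"] = None
        out["flag"] = f"collinear predictors (r={r:.4f}); joint model skipped"
        return out
    design = np.column_stack([cls, ind] if cov is None else [cls, ind, cov])
    f = LogisticRegressionIRLS().fit(design, y)
    out["joint"] = {
        "classical": AssociationResult(float(f.coef_[1]), float(f.se_[1]),
                                       float(f.pvalues_[1]), "conditional",
                                       int(y.size)),
        "indel": AssociationResult(float(f.coef_[2]), float(f.se_[2]),
                                   float(f.pvalues_[2]), "conditional",
                                   int(y.size)),
    }
    out["flag"] = f"predictor LD r={r:.3f}" if abs(r) > 0.5 else None
    return out
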