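"""Two-locus haplotype analysis: phasing EM, LD statistics, and genetic-model
dissection (conditional signals, dominance vs additivity, haplotype-defining
marker sets compared by BIC)."""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .association import AssociationResult, LogisticRegressionIRLS
from .simulate import HAPLOTYPES, HaplotypeTable

# Diplotype compatibility: genotype pair (g1, g2) in 0/1/2 -> list of
# (hap_i, hap_j) unordered pairs; haplotype index order is HAPLOTYPES.
_HAP_GENO = {i: g for i, g in enumerate([(1, 1), (1, 0), (0, 1), (0, 0)])}


class MonomorphicLocusError(ValueError):
    pass


@dataclass
class LDStats:
    """Pairwise LD between the indel and the SNP risk alleles."""

    D: float
    d_prime: float
    r2: float


def ld_statistics(table: HaplotypeTable) -> LDStats:
    """D, D' and r^2 from a four-haplotype frequency table."""
    p, q = table.p_del, table.q_A
    if min(p, 1 - p, q, 1 - q) <= 0:
        raise MonomorphicLocusError("LD undefined for a monomorphic locus")
    D = table.freq_delA - p * q
    if D >= 0:
        d_max = min(p * (1 - q), (1 - p) * q)
    else:
        d_max = min(p * q, (1 - p) * (1 - q))
    d_prime = abs(D) / d_max if d_max > 0 else 0.0
    r2 = D * D / (p * (1 - p) * q * (1 - q))
    return LDStats(D=float(D), d_prime=float(d_prime), r2=float(r2))


class TwoLocusPhaser(BaseEstimator):
    """EM estimation of four two-locus haplotype frequencies from unphased
    genotypes.

    Only double heterozygotes (1,1) are phase-ambiguous; their mass is split
    between del-A/TG-T and del-T/TG-A in proportion to the current frequency
    products. Attributes after ``fit``: ``haplotype_table_``, ``loglik_``,
    ``n_iter_``, ``loglik_path_``.
    """

    def __init__(self, max_iter=200, tol=1e-12):
        self.max_iter = max_iter
        self.tol = tol

    def fit(self, G, y=None):
        G = np.asarray(G, dtype=float)
        G = G[~np.isnan(G).any(axis=1)].astype(int)
        n = G.shape[0]
        if n < 20:
            raise ValueError(f"need >= 20 genotyped subjects, got {n}")
        g1, g2 = G[:, 0], G[:, 1]
        if np.ptp(g1) == 0 or np.ptp(g2) == 0:
            import warnings
            warnings.warn("monomorphic locus: degenerate haplotype table")
        # counts of the nine genotype classes
        counts = np.zeros((3, 3))
        for a in range(3):
            for b in range(3):
                counts[a, b] = np.sum((g1 == a) & (g2 == b))
        n_dh = counts[1, 1]

        # unambiguous haplotype counts contributed by the other 8 classes
        fixed = np.zeros(4)  # delA, delT, TGA, TGT
        contrib = {  # (g1,g2) -> haplotype count vector per subject
            (0, 0): (0, 0, 0, 2), (0, 1): (0, 0, 1, 1), (0, 2): (0, 0, 2, 0),
            (1, 0): (0, 1, 0, 1), (1, 2): (1, 0, 1, 0),
            (2, 0): (0, 2, 0, 0), (2, 1): (1, 1, 0, 0), (2, 2): (2, 0, 0, 0),
        }
        for (a, b), vec in contrib.items():
            fixed += counts[a, b] * np.asarray(vec, float)

        f = np.full(4, 0.25)
        path = []
        ll = -np.inf
        for it in range(1, self.max_iter + 1):
            # E: split double-het mass between cis (delA/TGT) and trans (delT/TGA)
            cis = f[0] * f[3]
            trans = f[1] * f[2]
            w_cis = cis / (cis + trans) if cis + trans > 0 else 0.5
            hap = fixed.copy()
            hap += n_dh * np.array([w_cis, 1 - w_cis, 1 - w_cis, w_cis])
            f_new = hap / (2 * n)
            ll_new = self._loglik(counts, f_new)
            path.append(ll_new)
            f = f_new
            if np.isfinite(ll) and ll_new - ll <= self.tol * max(abs(ll), 1.0):
                break
            ll = ll_new
        self.haplotype_table_ = HaplotypeTable(*np.maximum(f, 0.0) / np.maximum(f, 0.0).sum())
        self.loglik_ = path[-1]
        self.loglik_path_ = path
        self.n_iter_ = it
        self.n_ = n
        return self

    @staticmethod
    def _loglik(counts, f):
        probs = {
            (0, 0): f[3] ** 2, (0, 1): 2 * f[2] * f[3], (0, 2): f[2] ** 2,
            (1, 0): 2 * f[1] * f[3], (1, 1): 2 * (f[0] * f[3] + f[1] * f[2]),
            (1, 2): 2 * f[0] * f[2],
            (2, 0): f[1] ** 2, (2, 1): 2 * f[0] * f[1], (2, 2): f[0] ** 2,
        }
        ll = 0.0
        for key, pr in probs.items():
            c = counts[key]
            if c > 0:
                ll += c * math.log(max(pr, 1e-300))
        return ll

    def predict_proba(self, G) -> pd.DataFrame:
        """Per-subject diplotype posteriors and the most likely diplotype."""
        f = self.haplotype_table_.freqs
        cis = f[0] * f[3]
        trans = f[1] * f[2]
        w = cis / (cis + trans) if cis + trans > 0 else 0.5
        dip_unambig = {
            (0, 0): "TG-T/TG-T", (0, 1): "TG-A/TG-T", (0, 2): "TG-A/TG-A",
            (1, 0): "del-T/TG-T", (1, 2): "del-A/TG-A",
            (2, 0): "del-T/del-T", (2, 1): "del-A/del-T", (2, 2): "del-A/del-A",
        }
        rows = []
        for g1, g2 in np.asarray(G, dtype=int):
            if (g1, g2) == (1, 1):
                rows.append({"diplotype": "del-A/TG-T" if w >= 0.5 else "del-T/TG-A",
                             "p_cis": w, "p_trans": 1 - w})
            else:
                rows.append({"diplotype": dip_unambig[(g1, g2)],
                             "p_cis": 1.0, "p_trans": 0.0})
        return pd.DataFrame(rows)

    def risk_haplotype_dosage(self, G, hard: bool = True) -> np.ndarray:
        """del-A copy number per subject: most-likely diplotype (default) or
        posterior-weighted dosage."""
        f = self.haplotype_table_.freqs
        cis = f[0] * f[3]
        trans = f[1] * f[2]
        w = cis / (cis + trans) if cis + trans > 0 else 0.5
        G = np.asarray(G, dtype=int)
        # del-A copies for unambiguous classes = max(0, g1 + g2 - 2) except
        # enumerate directly for clarity
        copies_map = {
            (0, 0): 0, (0, 1): 0, (0, 2): 0, (1, 0): 0, (1, 2): 1,
            (2, 0): 0, (2, 1): 1, (2, 2): 2,
        }
        out = np.empty(G.shape[0])
        for i, (g1, g2) in enumerate(G):
            if (g1, g2) == (1, 1):
                out[i] = (1.0 if w >= 0.5 else 0.0) if hard else w
            else:
                out[i] = copies_map[(g1, g2)]
        return out


def phase_two_locus(genotypes=None, *, phased_haplotypes=None) -> TwoLocusPhaser:
    """Estimate the haplotype table from unphased (g_indel, g_snp) pairs, or
    count directly when phased haplotype names are supplied."""
    if phased_haplotypes is not None:
        haps = np.asarray(phased_haplotypes).ravel()
        idx = {h: i for i, h in enumerate(HAPLOTYPES)}
        counts = np.zeros(4)
        for h in haps:
            counts[idx[h]] += 1
        phaser = TwoLocusPhaser()
        phaser.haplotype_table_ = HaplotypeTable(*(counts / counts.sum()))
        phaser.loglik_ = float(np.sum(
            counts[counts > 0] * np.log(counts[counts > 0] / counts.sum())))
        phaser.loglik_path_ = [phaser.loglik_]
        phaser.n_iter_ = 0
        phaser.n_ = haps.size // 2
        return phaser
    return TwoLocusPhaser().fit(np.asarray(genotypes))


def conditional_association(y, g1, g2, covariates=None, alpha: float = 0.05,
                            collinearity_r: float = 0.999):
    """Joint logistic model of both variants; each Wald p is conditional on
    the other. ``same_signal`` is True when both conditional p > alpha (the
    two variants cannot improve each other) or when they are collinear."""
    y = np.asarray(y, float).ravel()
    g1 = np.asarray(g1, float).ravel()
    g2 = np.asarray(g2, float).ravel()
    for name, g in (("g1", g1), ("g2", g2)):
        if np.std(g) == 0:
            raise MonomorphicLocusError(f"{name} is monomorphic")
    r = np.corrcoef(g1, g2)[0, 1]
    if abs(r) > collinearity_r:
        res = AssociationResult(np.nan, np.nan, np.nan, "conditional",
                                flag=f"collinear (r={r:.4f})")
        return {"g1": res, "g2": res, "same_signal": True,
                "reason": "collinear predictors"}
    cov = None if covariates is None else np.asarray(covariates, float)
    design = np.column_stack([g1, g2] if cov is None else [g1, g2, cov])
    fit = LogisticRegressionIRLS().fit(design, y)
    out = {}
    for j, name in enumerate(("g1", "g2"), start=1):
        out[name] = AssociationResult(
            beta=float(fit.coef_[j]), se=float(fit.se_[j]),
            p=float(fit.pvalues_[j]), test="conditional", n_eff=int(y.size),
            flag="separation" if fit.separation_ else None)
    out["same_signal"] = bool(out["g1"].p > alpha and out["g2"].p > alpha)
    out["reason"] = None
    return out


@dataclass
class ModelFit:
    label: str
    coding: str
    coef: dict
    se: dict
    loglik: float
    k: int
    n: int

    @property
    def bic(self) -> float:
        return -2.0 * self.loglik + self.k * math.log(self.n)


@dataclass
class ModelComparison:
    fits: list
    winner: str
    dominance_p: float | None = None
    flag: str | None = None

    def bic_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"model": f.label, "loglik": f.loglik, "k": f.k, "bic": f.bic,
              "winner": f.label == self.winner} for f in self.fits]
        )

    def fit(self, label: str) -> ModelFit:
        return next(f for f in self.fits if f.label == label)


def _logistic_model(label, coding_desc, y, terms: dict, cov, n):
    names = list(terms)
    cols = [np.asarray(terms[t], float) for t in names]
    design = np.column_stack(cols + ([cov] if cov is not None else []))
    fit = LogisticRegressionIRLS().fit(design, y)
    coef = {"intercept": fit.coef_[0]}
    se = {"intercept": fit.se_[0]}
    for j, t in enumerate(names, start=1):
        coef[t] = float(fit.coef_[j])
        se[t] = float(fit.se_[j])
    return ModelFit(label=label, coding=coding_desc, coef=coef, se=se,
                    loglik=fit.loglik_, k=fit.k_, n=n), fit


def dominance_model_comparison(y, hap_copies, covariates=None) -> ModelComparison:
    """Additive (0/1/2) vs additive+dominance vs complete dominance (0/1/1).

    Mirrors the two-step decision: the dominance term is tested by Wald within
    the additive+dominance model, then complete dominance and
    additive+dominance are compared by BIC. All three fits share the same
    covariates and subjects so BIC differences reflect genetic terms only.
    """
    y = np.asarray(y, float).ravel()
    h = np.asarray(hap_copies, float).ravel()
    cov = None if covariates is None else np.asarray(covariates, float)
    n = y.size
    flag = None
    class_counts = [(h == c).sum() for c in (0, 1, 2)]
    if class_counts[2] == 0:
        flag = "no homozygous carriers: additive and dominance indistinguishable"
    elif min(class_counts) < 5:
        flag = f"sparse copy classes {class_counts}"

    het = (h == 1).astype(float)
    add, _ = _logistic_model("additive", "0/1/2", y, {"copies": h}, cov, n)
    cdom, _ = _logistic_model("complete_dominance", "0/1/1", y,
                              {"carrier": (h >= 1).astype(float)}, cov, n)
    if class_counts[2] == 0:
        # het indicator coincides with the additive coding: the three models
        # collapse to one and the dominance term cannot be estimated
        dominance_p = None
        fits = [add, cdom]
    else:
        adddom, f2 = _logistic_model("additive+dominance", "0/1/2 + het",
                                     y, {"copies": h, "het": het}, cov, n)
        dominance_p = float(f2.pvalues_[2])
        fits = [add, adddom, cdom]
    winner = min(fits, key=lambda f: f.bic).label
    return ModelComparison(fits=fits, winner=winner, dominance_p=dominance_p,
                           flag=flag)


def haplotype_model_selection(y, candidate_sets: dict, covariates=None) -> ModelComparison:
    """BIC comparison of logistic models over candidate predictor sets.

    ``candidate_sets``: label -> DataFrame/2-D array of predictors; all sets
    must cover the identical subjects.
    """
    y = np.asarray(y, float).ravel()
    cov = None if covariates is None else np.asarray(covariates, float)
    n = y.size
    fits = []
    for label, preds in candidate_sets.items():
        arr = np.asarray(preds, float)
        if arr.ndim == 1:
            arr = arr[:, None]
        if arr.shape[0] != n:
            raise ValueError(
                f"candidate set {label!r} covers {arr.shape[0]} subjects, "
                f"expected {n}; all sets must use the identical subject set")
        terms = {f"x{j}": arr[:, j] for j in range(arr.shape[1])}
        if isinstance(preds, pd.DataFrame):
            terms = {c: preds[c].to_numpy(float) for c in preds.columns}
        fit, _ = _logistic_model(label, "custom", y, terms, cov, n)
        fits.append(fit)
    winner = min(fits, key=lambda f: f.bic).label
    return ModelComparison(fits=fits, winner=winner)
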