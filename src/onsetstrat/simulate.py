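"""Synthetic case-control cohorts with a two-locus risk haplotype and bimodal onset.

The generator emulates the statistical structure of an onset-stratified
association study of an autoimmune skin disease: a rare indel risk allele
("del", control frequency ~3.5%) in near-complete LD (D' ~ 0.98) with a common
SNP risk allele ("A", frequency ~42.7%); the haplotype carrying both risk
alleles ("del-A") acts as a dominant risk factor; onset ages are a mixture of
an early component N(10.3, 5.6^2) and a late component N(34.0, 14.5^2), with
the early component enriched among risk-haplotype carriers; plus population
strata, eigenvector-style covariates, a comorbidity flag, and an optional
classical-allele marker riding on the risk haplotype.

Case-control ascertainment uses rejection sampling from a prospective logistic
disease model, so the planted odds ratios are recovered by retrospective
logistic regression and control allele frequencies stay close to their
population values (baseline prevalence is kept low).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from ._utils import check_probability, stage_rng

# Haplotype order used everywhere: index 0 is the high-risk haplotype.
HAPLOTYPES = ("del-A", "del-T", "TG-A", "TG-T")
RISK_HAPLOTYPE = "del-A"

# Which haplotypes carry the indel deletion allele / the SNP A allele.
_DEL_HAPS = (0, 1)
_A_HAPS = (0, 2)

# Onset components shared by all carrier classes (years).
DEFAULT_ONSET_MEANS = (10.3, 34.0)
DEFAULT_ONSET_SDS = (5.6, 14.5)


class InfeasibleLDError(ValueError):
    """Requested allele frequencies and D' imply a negative haplotype frequency."""


class GenerationError(RuntimeError):
    """Case/control quota could not be filled within the draw cap."""


@dataclass(frozen=True)
class HaplotypeTable:
    """Four two-locus haplotype frequencies in the order ``HAPLOTYPES``."""

    freq_delA: float
    freq_delT: float
    freq_TGA: float
    freq_TGT: float

    @property
    def freqs(self) -> np.ndarray:
        return np.array([self.freq_delA, self.freq_delT, self.freq_TGA, self.freq_TGT])

    @property
    def p_del(self) -> float:
        return self.freq_delA + self.freq_delT

    @property
    def q_A(self) -> float:
        return self.freq_delA + self.freq_TGA

    def __post_init__(self):
        f = self.freqs
        if np.any(f < -1e-15):
            raise InfeasibleLDError(f"negative haplotype frequency in {f}")
        if abs(f.sum() - 1.0) > 1e-12:
            raise ValueError(f"haplotype frequencies sum to {f.sum()!r}, not 1")


def build_haplotype_table(p_del: float, q_A: float, d_prime: float) -> HaplotypeTable:
    """Four-haplotype table from allele frequencies and normalized LD.

    Uses the positive-D convention with the two risk alleles coupled:
    D = D' * min(p(1-q), (1-p)q), so the risk-risk haplotype is enriched.
    """
    p = check_probability("p_del", p_del)
    q = check_probability("q_A", q_A)
    check_probability("d_prime", d_prime, open_interval=False)
    d_max = min(p * (1 - q), (1 - p) * q)
    D = float(d_prime) * d_max
    freqs = (p * q + D, p * (1 - q) - D, (1 - p) * q - D, (1 - p) * (1 - q) + D)
    if min(freqs) < -1e-15:
        raise InfeasibleLDError(
            f"p_del={p}, q_A={q}, d_prime={d_prime} give haplotype frequencies {freqs}"
        )
    freqs = tuple(max(f, 0.0) for f in freqs)
    return HaplotypeTable(*freqs)


def early_weight_for_mean(target_mean: float,
                          means: Sequence[float] = DEFAULT_ONSET_MEANS) -> float:
    """Early-component weight that gives a two-component mixture the target mean.

    w = (mu_late - target) / (mu_late - mu_early).
    """
    lo, hi = means
    w = (hi - target_mean) / (hi - lo)
    return check_probability("early weight", w, open_interval=False)


# Derived so non-carrier cases average 29.3 y and carriers ~20.3 y of onset,
# matching the carrier-class means the generator is meant to reproduce.
DEFAULT_W_EARLY_NONCARRIER = early_weight_for_mean(29.3)
DEFAULT_W_EARLY_CARRIER = early_weight_for_mean(20.3)


@dataclass
class ScenarioConfig:
    """Parameters of one simulated cohort.

    Defaults are the study-scale conditions: control del frequency 3.5%,
    SNP A frequency 42.7%, D' = 0.98, a completely dominant risk haplotype
    with OR 8.10, and carrier-class onset mixtures over the shared early/late
    components.
    """

    p_del: float = 0.035
    q_A: float = 0.427
    d_prime: float = 0.98
    n_cases: int = 1100
    n_controls: int = 10000
    risk_model: str = "dominant"          # {"additive", "dominant"}
    odds_ratio: float = 8.10
    risk_on: str = "haplotype"            # {"haplotype", "indel", "snp"}
    odds_ratio_snp: float = 1.0           # extra per-A-allele effect (joint model)
    baseline_prevalence: float = 0.001
    onset_means: tuple = DEFAULT_ONSET_MEANS
    onset_sds: tuple = DEFAULT_ONSET_SDS
    w_early_carrier: float = DEFAULT_W_EARLY_CARRIER
    w_early_noncarrier: float = DEFAULT_W_EARLY_NONCARRIER
    n_strata: int = 3
    stratum_offsets: tuple = (-0.25, 0.0, 0.25)
    n_covariates: int = 2
    covariate_effects: tuple = (0.1, -0.1)
    comorbid_rate_early: float = 0.17
    comorbid_rate_late: float = 0.224
    comorbid_rate_controls: float = 0.10
    comorbid_or_classical: float = 1.0
    comorbid_or_indel: float = 1.0
    classical_on_risk: float = 0.98       # P(marker | risk haplotype)
    classical_on_nonrisk: float = 0.028   # P(marker | other haplotype)
    master_seed: int = 0
    max_draws: int = 1_000_000

    def __post_init__(self):
        check_probability("p_del", self.p_del)
        check_probability("q_A", self.q_A)
        check_probability("d_prime", self.d_prime, open_interval=False)
        check_probability("baseline_prevalence", self.baseline_prevalence)
        if self.n_cases <= 0 or self.n_controls <= 0:
            raise ValueError("n_cases and n_controls must be positive")
        if self.risk_model not in ("additive", "dominant"):
            raise ValueError(f"unknown risk_model {self.risk_model!r}")
        if self.risk_on not in ("haplotype", "indel", "snp"):
            raise ValueError(f"unknown risk_on {self.risk_on!r}")
        if self.odds_ratio <= 0 or self.odds_ratio_snp <= 0:
            raise ValueError("odds ratios must be positive")
        if any(s <= 0 for s in self.onset_sds):
            raise ValueError("onset SDs must be positive")
        if self.n_strata < 1 or len(self.stratum_offsets) != self.n_strata:
            raise ValueError("stratum_offsets must have length n_strata >= 1")
        if len(self.covariate_effects) != self.n_covariates:
            raise ValueError("covariate_effects must have length n_covariates")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "ScenarioConfig":
        with open(path) as fh:
            raw = json.load(fh)
        for key in ("onset_means", "onset_sds", "stratum_offsets", "covariate_effects"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class Cohort:
    """Simulated subjects plus the provenance needed to regenerate them.

    ``data`` columns: subject_id, hap1, hap2 (haplotype names), g_indel, g_snp,
    hap_copies (risk-haplotype count), classical_count, status, onset_age
    (NaN for controls), stratum, ev1..evK, comorbid, onset_component (latent
    early=0/late=1 for cases, -1 for controls; not persisted to disk).
    """

    data: pd.DataFrame
    config: ScenarioConfig | None = None

    @property
    def n_cases(self) -> int:
        return int((self.data["status"] == 1).sum())

    @property
    def n_controls(self) -> int:
        return int((self.data["status"] == 0).sum())

    @property
    def covariate_columns(self) -> list:
        return [c for c in self.data.columns if c.startswith("ev")]

    def cases(self) -> pd.DataFrame:
        return self.data[self.data["status"] == 1]

    def controls(self) -> pd.DataFrame:
        return self.data[self.data["status"] == 0]


def _risk_copies(h1: np.ndarray, h2: np.ndarray, risk_on: str) -> np.ndarray:
    if risk_on == "haplotype":
        return (h1 == 0).astype(int) + (h2 == 0).astype(int)
    if risk_on == "indel":
        return np.isin(h1, _DEL_HAPS).astype(int) + np.isin(h2, _DEL_HAPS).astype(int)
    return np.isin(h1, _A_HAPS).astype(int) + np.isin(h2, _A_HAPS).astype(int)


def simulate_cohort(config: ScenarioConfig) -> Cohort:
    """Draw a case-control cohort under the configured scenario.

    Haplotype pairs are drawn i.i.d. from the four-haplotype table; disease is
    assigned from a logistic model (baseline prevalence + stratum offset +
    covariates + genetic term); subjects are accumulated by rejection sampling
    until both quotas fill. Fully reproducible from ``master_seed``.
    """
    table = build_haplotype_table(config.p_del, config.q_A, config.d_prime)
    rng = stage_rng(config.master_seed, "cohort")
    beta_g = math.log(config.odds_ratio)
    base = logit(config.baseline_prevalence)
    offsets = np.asarray(config.stratum_offsets, dtype=float)
    cov_beta = np.asarray(config.covariate_effects, dtype=float)

    want = {"case": config.n_cases, "control": config.n_controls}
    parts = {"case": [], "control": []}
    got = {"case": 0, "control": 0}
    drawn = 0
    while got["case"] < want["case"] or got["control"] < want["control"]:
        if drawn >= config.max_draws:
            raise GenerationError(
                f"drew {drawn} subjects without filling quotas "
                f"(have {got['case']}/{want['case']} cases, "
                f"{got['control']}/{want['control']} controls); "
                "raise max_draws or baseline_prevalence"
            )
        m = min(100_000, config.max_draws - drawn)
        drawn += m
        h1 = rng.choice(4, size=m, p=table.freqs)
        h2 = rng.choice(4, size=m, p=table.freqs)
        stratum = rng.integers(0, config.n_strata, size=m)
        covs = rng.standard_normal((m, config.n_covariates))
        copies = _risk_copies(h1, h2, config.risk_on)
        coding = copies if config.risk_model == "additive" else (copies > 0).astype(int)
        eta = base + offsets[stratum] + (covs @ cov_beta if config.n_covariates else 0.0)
        eta = eta + beta_g * coding
        if config.odds_ratio_snp != 1.0:
            snp = np.isin(h1, _A_HAPS).astype(int) + np.isin(h2, _A_HAPS).astype(int)
            eta = eta + math.log(config.odds_ratio_snp) * snp
        is_case = rng.random(m) < expit(eta)
        for label, mask in (("case", is_case), ("control", ~is_case)):
            need = want[label] - got[label]
            if need <= 0:
                continue
            idx = np.flatnonzero(mask)[:need]
            parts[label].append((h1[idx], h2[idx], stratum[idx], covs[idx]))
            got[label] += idx.size

    def _stack(label):
        h1 = np.concatenate([p[0] for p in parts[label]])
        h2 = np.concatenate([p[1] for p in parts[label]])
        st = np.concatenate([p[2] for p in parts[label]])
        cv = np.vstack([p[3] for p in parts[label]]) if config.n_covariates else \
            np.empty((h1.size, 0))
        return h1, h2, st, cv

    ch1, ch2, cst, ccv = _stack("case")
    uh1, uh2, ust, ucv = _stack("control")
    h1 = np.concatenate([ch1, uh1])
    h2 = np.concatenate([ch2, uh2])
    stratum = np.concatenate([cst, ust])
    covs = np.vstack([ccv, ucv])
    status = np.concatenate([np.ones(ch1.size, int), np.zeros(uh1.size, int)])
    n = h1.size

    hap_copies = _risk_copies(h1, h2, "haplotype")
    g_indel = np.isin(h1, _DEL_HAPS).astype(int) + np.isin(h2, _DEL_HAPS).astype(int)
    g_snp = np.isin(h1, _A_HAPS).astype(int) + np.isin(h2, _A_HAPS).astype(int)

    # Onset ages for cases: carrier-class early-component weight, shared
    # components, truncated at zero by redrawing.
    onset_rng = stage_rng(config.master_seed, "onset")
    onset = np.full(n, np.nan)
    component = np.full(n, -1, dtype=int)
    case_mask = status == 1
    carrier = hap_copies[case_mask] >= 1
    w_early = np.where(carrier, config.w_early_carrier, config.w_early_noncarrier)
    comp = (onset_rng.random(case_mask.sum()) >= w_early).astype(int)  # 0=early,1=late
    mu = np.asarray(config.onset_means)[comp]
    sd = np.asarray(config.onset_sds)[comp]
    ages = onset_rng.normal(mu, sd)
    neg = ages < 0
    while neg.any():
        ages[neg] = onset_rng.normal(mu[neg], sd[neg])
        neg = ages < 0
    onset[case_mask] = ages
    component[case_mask] = comp

    # Classical-allele marker carried (noisily) on the risk haplotype.
    cls_rng = stage_rng(config.master_seed, "classical")
    p_emit = np.where(
        np.stack([h1, h2]) == 0, config.classical_on_risk, config.classical_on_nonrisk
    )
    classical = (cls_rng.random((2, n)) < p_emit).sum(axis=0)

    # Comorbidity: per-subgroup base rate, optionally modulated by the
    # classical marker and the indel allele count (protective ORs < 1).
    com_rng = stage_rng(config.master_seed, "comorbid")
    base_rate = np.where(
        status == 0,
        config.comorbid_rate_controls,
        np.where(component == 0, config.comorbid_rate_early, config.comorbid_rate_late),
    )
    eta_c = logit(base_rate)
    eta_c = eta_c + math.log(config.comorbid_or_classical) * (classical >= 1)
    eta_c = eta_c + math.log(config.comorbid_or_indel) * g_indel
    comorbid = (com_rng.random(n) < expit(eta_c)).astype(int)

    data = pd.DataFrame({
        "subject_id": [f"S{i + 1:06d}" for i in range(n)],
        "hap1": [HAPLOTYPES[i] for i in h1],
        "hap2": [HAPLOTYPES[i] for i in h2],
        "g_indel": g_indel,
        "g_snp": g_snp,
        "hap_copies": hap_copies,
        "classical_count": classical,
        "status": status,
        "onset_age": onset,
        "stratum": stratum,
    })
    for k in range(config.n_covariates):
        data[f"ev{k + 1}"] = covs[:, k]
    data["comorbid"] = comorbid
    data["onset_component"] = component
    return Cohort(data=data, config=config)


def sample_onset_mixture(n: int, weights=(0.384, 0.616),
                         means: Sequence[float] = DEFAULT_ONSET_MEANS,
                         sds: Sequence[float] = DEFAULT_ONSET_SDS,
                         seed=None, truncate_at_zero: bool = False) -> np.ndarray:
    """Draw ages from a K-component normal mixture.

    By default the plain mixture is sampled (the distribution the mixture EM
    assumes); ``truncate_at_zero`` redraws negatives, which slightly inflates
    component means and is what the cohort generator uses for onset ages.
    """
    rng = np.random.default_rng(seed)
    w = np.asarray(weights, float)
    comp = rng.choice(w.size, size=n, p=w / w.sum())
    mu = np.asarray(means, float)[comp]
    sd = np.asarray(sds, float)[comp]
    ages = rng.normal(mu, sd)
    if truncate_at_zero:
        neg = ages < 0
        while neg.any():
            ages[neg] = rng.normal(mu[neg], sd[neg])
            neg = ages < 0
    return ages


# Diplotype classes of the expression panel, with subject counts mirroring the
# genotype-selected design of the surface-protein study (n = 46).
EXPRESSION_PANEL_DIPLOTYPES = (
    ("TG-T", "TG-T", 13),
    ("TG-T", "TG-A", 12),
    ("TG-A", "TG-A", 8),
    ("TG-T", "del-A", 8),
    ("TG-A", "del-A", 4),
    ("del-A", "del-A", 1),
)


def simulate_expression_panel(
    seed: int = 0,
    *,
    dq_effect: float = 350.0,
    dr_effect: float = 0.0,
    noise_sd: float = 250.0,
    cell_types: Sequence[str] = ("monocyte", "dendritic"),
) -> pd.DataFrame:
    """Surface-protein MFI panel keyed by two-locus diplotype.

    A per-risk-haplotype-copy shift is planted for HLA-DQ only (``dq_effect``),
    HLA-DR stays flat by default, emulating an analyte-specific genotype effect.
    Returns long-format records: subject, cell_type, analyte, mfi, plus allele
    and haplotype counts usable as regression predictors.
    """
    rng = stage_rng(seed, "expression")
    rows = []
    base = {"monocyte": 1500.0, "dendritic": 1200.0, "B": 2000.0, "T": 300.0}
    sid = 0
    for hap_a, hap_b, count in EXPRESSION_PANEL_DIPLOTYPES:
        for _ in range(count):
            sid += 1
            haps = (hap_a, hap_b)
            hap_count = sum(h == RISK_HAPLOTYPE for h in haps)
            del_count = sum(h.startswith("del") for h in haps)
            a_count = sum(h.endswith("-A") for h in haps)
            for ct in cell_types:
                for analyte, eff in (("HLA-DQ", dq_effect), ("HLA-DR", dr_effect)):
                    mfi = base[ct] + eff * hap_count + noise_sd * rng.standard_normal()
                    rows.append({
                        "subject": f"E{sid:03d}", "cell_type": ct, "analyte": analyte,
                        "mfi": max(mfi, 1.0), "hap_count": hap_count,
                        "del_count": del_count, "a_count": a_count,
                    })
    return pd.DataFrame(rows)
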