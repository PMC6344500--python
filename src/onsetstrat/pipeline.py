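"""End-to-end orchestration: simulate -> mixture -> classify -> stratified
scans -> contrast -> haplotype models -> variance explained -> onset profile ->
comorbidity -> expression, with deterministic seeds and per-stage reports."""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as cio
from ._utils import stage_rng
from .association import association_scan
from .comorbidity import protective_association, subgroup_comorbidity_contrast
from .contrast import contrast_scan
from .expression import expression_genotype_regression
from .haplotypes import dominance_model_comparison, ld_statistics, phase_two_locus
from .mixture import classify_subgroups, select_components
from .profile import carrier_onset_summary, haplotype_frequency_profile
from .simulate import Cohort, ScenarioConfig, simulate_cohort, simulate_expression_panel
from .variance import variant_variance_contribution

log = logging.getLogger("onsetstrat.pipeline")

SUMMARY_SCHEMA_VERSION = 1

DEFAULT_STAGES = ("simulate", "mixture", "classify", "scan", "contrast",
                  "haplotype_models", "variance", "profile", "comorbidity",
                  "expression")


class StageError(RuntimeError):
    def __init__(self, stage, err):
        super().__init__(f"pipeline stage {stage!r} failed: {err}")
        self.stage = stage


@dataclass
class RunConfig:
    scenario: ScenarioConfig = field(default_factory=ScenarioConfig)
    out_dir: str = "onsetstrat_run"
    stages: tuple = DEFAULT_STAGES
    posterior_threshold: float = 0.8
    genome_wide_p: float = 5e-8
    contrast_p: float = 5e-5
    conditional_p: float = 0.05
    total_h2: dict = field(default_factory=lambda: {"early": 0.55, "late": 0.40})
    mixture_restarts: int = 20
    k_max: int = 7
    seed: int = 0

    def __post_init__(self):
        for name, v in (("posterior_threshold", self.posterior_threshold),
                        ("conditional_p", self.conditional_p)):
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0,1)")
        if not 0 < self.genome_wide_p <= 5e-8:
            raise ValueError("genome_wide_p must be in (0, 5e-8]")

    def to_json(self, path):
        d = dataclasses.asdict(self)
        with open(path, "w") as fh:
            json.dump(d, fh, indent=2, default=str)

    @classmethod
    def from_json(cls, path):
        with open(path) as fh:
            raw = json.load(fh)
        if "scenario" in raw and isinstance(raw["scenario"], dict):
            sc = raw["scenario"]
            for key in ("onset_means", "onset_sds", "stratum_offsets",
                        "covariate_effects"):
                if key in sc:
                    sc[key] = tuple(sc[key])
            raw["scenario"] = ScenarioConfig(**sc)
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(**raw)


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages in order; write per-stage artifacts and a
    combined ``summary.json`` into the run directory. Deterministic given the
    config seeds; partial outputs are retained when a stage fails."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_json(out / "run_config.json")
    summary = {"schema_version": SUMMARY_SCHEMA_VERSION, "seed": config.seed}
    cohort: Cohort | None = None
    labels = None

    def _stage(name):
        return name in config.stages

    def _run(name, fn):
        t0 = time.perf_counter()
        try:
            res = fn()
        except Exception as err:  # halt with a stage-named error
            raise StageError(name, err) from err
        dt = time.perf_counter() - t0
        log.info("stage=%s seed=%s runtime=%.2fs", name, config.seed, dt)
        return res

    if _stage("simulate"):
        def _simulate():
            sc = dataclasses.replace(config.scenario, master_seed=config.seed)
            c = simulate_cohort(sc)
            cio.write_cohort(c, out / "genotypes.vcf", out / "phenotypes.tsv")
            return c
        cohort = _run("simulate", _simulate)
        summary["simulate"] = {"n_cases": cohort.n_cases,
                               "n_controls": cohort.n_controls}

    if cohort is None:
        raise StageError("simulate", "later stages need a cohort; enable 'simulate'")
    cases = cohort.cases()
    ages = cases["onset_age"].to_numpy(float)

    if _stage("mixture"):
        fit = _run("mixture", lambda: select_components(
            ages, k_max=config.k_max, restarts=config.mixture_restarts,
            seed=config.seed))
        summary["mixture"] = {
            "K": fit.n_components_, "weights": fit.weights_.tolist(),
            "means": fit.means_.tolist(), "sds": fit.sds_.tolist(),
            "loglik": fit.loglik_, "bic": fit.bic_,
            "bic_trace": {str(k): v for k, v in fit.bic_trace_.items()},
        }
        (out / "mixture_fit.json").write_text(
            json.dumps(_jsonable(summary["mixture"]), indent=2))
    else:
        fit = None

    if _stage("classify"):
        if fit is None or fit.n_components_ != 2:
            from .mixture import fit_gaussian_mixture
            fit2 = fit_gaussian_mixture(ages, 2, restarts=config.mixture_restarts,
                                        seed=config.seed)
        else:
            fit2 = fit
        assign = _run("classify", lambda: classify_subgroups(
            fit2, ages, threshold=config.posterior_threshold))
        labels = assign.labels.to_numpy()
        assign.assignments.assign(subject_id=cases["subject_id"].to_numpy()) \
            .to_csv(out / "subgroup_assignments.tsv", sep="\t", index=False)
        summary["classify"] = {
            "threshold": config.posterior_threshold,
            "n_early": int((labels == "early").sum()),
            "n_late": int((labels == "late").sum()),
            "n_unassigned": int((labels == "unassigned").sum()),
            "boundaries": assign.boundaries,
        }

    geno_cols = ["g_indel", "g_snp"]
    scans = {}
    if _stage("scan"):
        if labels is None:
            raise StageError("scan", "needs the classify stage")
        def _scan():
            ctrl = cohort.controls()
            # controls split between subgroups proportionally to case counts,
            # deterministically from the run seed
            rng = stage_rng(config.seed, "control-split")
            n_early = (labels == "early").sum()
            n_late = (labels == "late").sum()
            frac_early = n_early / max(n_early + n_late, 1)
            to_early = rng.random(len(ctrl)) < frac_early
            res = {}
            for sub, mask in (("early", labels == "early"),
                              ("late", labels == "late")):
                sub_cases = cases[mask]
                sub_ctrl = ctrl[to_early if sub == "early" else ~to_early]
                dat = pd.concat([sub_cases, sub_ctrl])
                res[sub] = association_scan(
                    (dat["status"] == 1).astype(int).to_numpy(),
                    dat[geno_cols], strata=dat["stratum"].to_numpy(),
                    gw_threshold=config.genome_wide_p)
            return res
        scans = _run("scan", _scan)
        for sub, scan in scans.items():
            scan.table.to_csv(out / f"scan_{sub}.tsv", sep="\t", index=False)
        summary["scan"] = {
            sub: {"lambda": scan.lambda_,
                  "results": scan.table[["variant", "or", "p", "genome_wide"]]
                  .to_dict("records")}
            for sub, scan in scans.items()}

    if _stage("contrast") and scans:
        contrasts, only = _run("contrast", lambda: contrast_scan(
            scans["early"], scans["late"], threshold=config.contrast_p))
        contrasts.to_csv(out / "contrast.tsv", sep="\t", index=False)
        summary["contrast"] = {"table": contrasts.to_dict("records"),
                               "unshared": only}

    if _stage("haplotype_models"):
        def _hap():
            y = cohort.data["status"].to_numpy(float)
            phaser = phase_two_locus(cohort.data[geno_cols].to_numpy())
            ld = ld_statistics(phaser.haplotype_table_)
            comp = dominance_model_comparison(
                y, cohort.data["hap_copies"].to_numpy(float),
                covariates=cohort.data[cohort.covariate_columns].to_numpy(float)
                if cohort.covariate_columns else None)
            return phaser, ld, comp
        phaser, ld, comp = _run("haplotype_models", _hap)
        summary["haplotype_models"] = {
            "haplotype_freqs": phaser.haplotype_table_.freqs.tolist(),
            "ld": {"D": ld.D, "d_prime": ld.d_prime, "r2": ld.r2},
            "dominance": {"winner": comp.winner, "dominance_p": comp.dominance_p,
                          "bic": comp.bic_table().to_dict("records")},
        }
        (out / "haplotype_models.json").write_text(
            json.dumps(_jsonable(summary["haplotype_models"]), indent=2))

    if _stage("variance") and labels is not None:
        def _variance():
            res = {}
            ctrl = cohort.controls()
            for sub in ("early", "late"):
                sub_cases = cases[labels == sub]
                dat = pd.concat([sub_cases, ctrl])
                y = (dat["status"] == 1).astype(float).to_numpy()
                cov = dat[cohort.covariate_columns].to_numpy(float) \
                    if cohort.covariate_columns else None
                sets = {
                    "indel": dat["g_indel"].to_numpy(float),
                    "snp": dat["g_snp"].to_numpy(float),
                    "both": dat[geno_cols].to_numpy(float),
                }
                res[sub] = variant_variance_contribution(
                    y, cov, sets, total_h2=config.total_h2[sub])
            return res
        var = _run("variance", _variance)
        summary["variance"] = {
            sub: {lab: {"delta_r2": vc.delta, "fraction_of_h2": vc.fraction_of_h2}
                  for lab, vc in d.items()} for sub, d in var.items()}

    if _stage("profile"):
        prof = _run("profile", lambda: haplotype_frequency_profile(
            ages, cases["hap_copies"].to_numpy(float)))
        prof.to_csv(out / "onset_profile.tsv", sep="\t", index=False)
        summary["profile"] = {
            "carrier_summary": carrier_onset_summary(
                ages, cases["hap_copies"].to_numpy(int)),
        }

    if _stage("comorbidity") and labels is not None:
        def _com():
            tab = subgroup_comorbidity_contrast(labels,
                                                cases["comorbid"].to_numpy(int))
            prot = None
            cls = (cases["classical_count"] >= 1).astype(float).to_numpy()
            ind = cases["g_indel"].to_numpy(float)
            if cls.std() > 0 and ind.std() > 0:
                prot = protective_association(cases["comorbid"].to_numpy(int),
                                              cls, ind)
            return tab, prot
        tab, prot = _run("comorbidity", _com)
        summary["comorbidity"] = {
            "counts": tab.counts.tolist(),
            "frequencies": tab.frequencies.tolist(),
            "p_fisher": tab.p_fisher,
        }
        if prot is not None:
            summary["comorbidity"]["protective"] = {
                k: {"or": v.or_, "p": v.p} for k, v in prot.items()
                if hasattr(v, "or_")}

    if _stage("expression"):
        def _expr():
            panel = simulate_expression_panel(seed=config.seed)
            res = {}
            for (ct, an), sub in panel.groupby(["cell_type", "analyte"]):
                r = expression_genotype_regression(sub, predictor="hap_count")
                res[f"{ct}:{an}"] = {"slope": r.slope, "se": r.se, "p": r.p}
            return panel, res
        panel, res = _run("expression", _expr)
        panel.to_csv(out / "expression_panel.tsv", sep="\t", index=False)
        summary["expression"] = res

    summary_path = out / "summary.json"
    summary_path.write_text(json.dumps(_jsonable(summary), indent=2,
                                       sort_keys=True))
    return summary
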