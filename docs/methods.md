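# Methods

## The analysis model

`onsetstrat` implements an onset-stratified case-control association
analysis. The phenotype side assumes case age-of-onset arises from a finite
mixture of normal components; the genetic side assumes a biallelic rare
variant (an indel, risk allele "del") and a common SNP (risk allele "A")
whose risk alleles are coupled on one haplotype ("del-A") in near-complete
LD, with disease risk acting through a logistic model on a genotype coding
(additive 0/1/2, or dominant/carrier 0/1/1). The stages are deliberately
modular: each can be used on real tabular inputs (VCF + phenotype TSV), and
all of them are exercised end-to-end on synthetic cohorts.

### Onset mixture

Ages a_i are modelled as Σ_k w_k N(μ_k, σ_k²). EM maximizes the likelihood
for fixed K; K is selected by BIC with parameter count 3K−1 (K−1 free
weights, K means, K SDs). The number of free parameters used by the original
software behind published fits of this kind is not generally documented;
3K−1 is the standard count for a fully free univariate normal mixture and is
recomputed independently in the tests. Numerical choices:

- Initialization: one deterministic quantile-split start (sorted ages cut
  into K blocks; block means, pooled SD, uniform weights) plus `n_init − 1`
  random starts seeded from `random_state` (means drawn without replacement
  from the observed values). Default 50 restarts for a fixed-K fit.
- Convergence: relative log-likelihood change below `tol` (default 1e-7);
  iteration cap 300. The per-iteration log-likelihood path is retained and
  its monotonicity asserted (tolerance 1e-9 relative) in the tests.
- A variance floor σ ≥ 0.1 y prevents component collapse onto single
  observations; BIC ties break toward smaller K; components are reported in
  ascending mean order.
- Fits with n < 5K are refused; in model selection such K are skipped and
  annotated in the BIC trace.

Subgroup classification needs K = 2 and labels a case early/late only when
its component posterior exceeds the threshold (default 0.8), else
"unassigned". Boundaries are reported as the contiguous integer ages where
each label would apply. Classification defaults to one pooled fit; nothing
prevents fitting per batch/cohort and classifying each separately, which is
how multi-cohort studies with differing per-cohort boundaries arise.

### Association

- CMH: per-stratum 2×2 allele-count tables (two chromosomes per subject),
  Mantel–Haenszel common OR, Robins–Breslow–Greenland SE and the 1-df
  chi-square test without continuity correction (via statsmodels
  `StratifiedTable`). Strata with a zero margin are dropped with a logged
  warning. Allele-level rather than genotype-level tables are used; with one
  stratum the test reduces exactly to the crude allelic 2×2 test.
- Logistic regression: IRLS (Newton scoring) with Wald SEs from the inverse
  observed information, convergence tolerance 1e-10 on the step, cap 100
  iterations. Suspected complete separation — any |β| > 15, plausible in
  rare-allele subgroup scans — is flagged on the result, never silent.
- X-chromosome option: under complete X-inactivation with equal effect sizes
  by sex, male genotypes at X variants enter doubled (0/2).
- Genomic inflation: λ = median(χ²) / F⁻¹_{χ²₁}(0.5). On a null scan of
  independent variants λ concentrates near 1 (the Wald statistic is mildly
  anti-conservative at moderate n, so values a few percent above 1 are
  expected).
- Effect-size contrast: Z = (β₁−β₂)/√(SE₁²+SE₂²), two-sided normal p. The
  variance assumes disjoint subgroup samples; covariance-aware contrasts for
  overlapping samples are out of scope.

### Two-locus haplotypes

The phasing EM estimates the four haplotype frequencies from unphased
genotype pairs; only double heterozygotes are ambiguous and their mass is
split between the cis (del-A/TG-T) and trans (del-T/TG-A) resolutions each
E-step. Phased input bypasses EM and counts directly. For model fitting,
haplotype copy number uses the most likely diplotype (hard assignment):
with D′ near 1 the double-heterozygote ambiguity is negligible;
posterior-weighted dosage is available (`risk_haplotype_dosage(hard=False)`).

Dominance dissection mirrors the two-step published procedure: fit additive
plus a heterozygote dominance term and test that term by Wald; then compare
complete dominance (0/1/1) against additive+dominance by BIC. All compared
models share the same subjects, intercept and covariates so BIC differences
reflect genetic terms only. With no homozygous carriers the three codings
collapse and the comparison is flagged as indeterminate. Candidate
haplotype-defining marker sets are compared by BIC on the identical subject
set; differing subject sets are an error, not a silent reindex.

### Variance explained

McFadden pseudo-r² = 1 − LL_model/LL_null with the intercept-only null; the
contribution of a variant set is the difference between the covariates+set
and covariates-only models. Total h² is an input constant (estimating it
requires genome-wide data and belongs to GREML-type tooling, out of scope);
`fraction_of_h2 = Δr²/h²` scales inversely with the supplied total exactly.
Pseudo-r² is computed on the observed case-control scale; no
liability-scale or ascertainment correction is applied.

### Profiles, comorbidity, expression

Onset profiles count chromosomes (2 per case) in left-closed 1-year bins up
to a 60-year cap, with exact Clopper–Pearson 95% CIs from beta quantiles;
empty bins are emitted with CI [0, 1]. The comorbidity contrast uses the
two-sided Fisher exact test with the "as or less probable" summation (the
dominant convention). Expression association is OLS of MFI on allele or
haplotype counts, one stream per cell type × analyte, with an optional
conditioning predictor; allele-specific expression is summarized as
per-allele percentages and one-decimal total fold-changes against a
designated reference subject.

## The synthetic cohort generator

The generator is first-class, tested code. Defaults are the study-scale
conditions the analysis is meant to face:

| parameter | default | meaning |
|---|---|---|
| p_del, q_A | 0.035, 0.427 | population risk-allele frequencies |
| d_prime | 0.98 | coupling of the two risk alleles (positive-D convention) |
| risk model | dominant, OR 8.10 | carrier odds multiplier on the del-A haplotype |
| baseline prevalence | 0.001 | non-carrier disease probability at covariate zero |
| onset components | N(10.3, 5.6²), N(34.0, 14.5²) | shared early/late components (years) |
| early weight | 0.578 carriers / 0.198 non-carriers | derived from target class means 20.3 / 29.3 y |
| strata | 3, offsets (−0.25, 0, 0.25) | population-structure baseline shifts |
| covariates | 2, effects (0.1, −0.1) | eigenvector-style standard-normal covariates |
| comorbidity | 0.17 early / 0.224 late / 0.10 controls | per-subgroup base rates |
| classical marker | 0.98 on-risk / 0.028 off-risk emission | companion classical allele in strong LD |

Haplotype pairs are drawn i.i.d. from the four-haplotype table
(pq+D, p(1−q)−D, (1−p)q−D, (1−p)(1−q)+D with D = D′·min(p(1−q), (1−p)q);
an infeasible combination raises rather than clipping silently). Disease is
assigned prospectively by a logistic model and case/control quotas are
filled by rejection sampling (cap 10⁶ draws by default) — this matches a
case-control design without committing to a population prevalence, keeps the
planted odds ratios recoverable by retrospective logistic regression, and,
because the baseline prevalence is low, leaves control allele frequencies
within sampling error of their population values. One master seed drives
named, independently derived child streams (cohort, onset, comorbidity,
classical marker), so identical configs reproduce byte-identical files and
adding a stage never perturbs the others.

Onset ages: each case draws its component by the carrier-class early weight,
then the component normal, redrawing negatives. The truncation raises the
realized mixture mean by about +0.4 y (mostly the late component's negative
tail at μ/σ ≈ 2.3). The closed-form weight derivation
w_early = (μ_late − target)/(μ_late − μ_early) is exact for the untruncated
mixture, so the EM-recovery and calibration experiments sample the plain
mixture, while cohort-level checks use tolerances that absorb the shift.

What the generator does **not** emulate: genome-wide variant panels and LD
beyond the two focal loci plus one companion marker; recombination;
imputation uncertainty; self-report error in onset ages (real onset data are
integer-valued and heaped); secondary risk factors, so the risk haplotype is
the *only* systematic case/control difference and case-level enrichments
(e.g. the haplotype frequency in the 5–9 y onset bins, ~30% here) are
stronger than in real cohorts where many loci share the risk. Passing tests
therefore demonstrate correctness of the estimators under the assumed model,
not robustness to real-data artefacts.

## Problem sizes and determinism

The recovery experiments run at the sizes the analysis design names: 4,523
onset ages for mixture EM; 1,100/10,000 (dominant) and 704/9,031 (additive)
case-control cohorts with 100 seeded replicates each; 20,000 haplotypes for
the LD round trip; 2,000 cases for onset calibration. Calibration suites use
1,000–2,000 replicates. All randomness flows from explicit seeds; the
pipeline re-run with the same config writes identical summaries.

## Known limitations

- The IRLS solver targets small, well-conditioned design matrices (a handful
  of variants and covariates); it is not a sparse/genome-wide engine.
- CMH is allele-level; genotype-level stratified tests are not implemented.
- Hard diplotype assignment slightly understates uncertainty when LD is weak
  — exactly the regime the posterior-dosage option exists for.
- The comorbidity model treats subgroup base rates as given; it does not
  model disease-specific comorbidity structure.
- Cluster/eigenvector derivation (the upstream population-structure step) is
  taken as input, simulated, or out of scope — stratum labels are never
  inferred here.
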