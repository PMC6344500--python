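# onsetstrat

Onset-stratified case-control genetic association analysis.

Many complex diseases are not one entity: cases with early onset can carry a
different (often stronger) genetic load than cases with late onset. A
motivating example is autoimmune vitiligo, where age-of-onset is bimodal and
an uncommon MHC class II indel allele — riding on a common-SNP background as a
two-locus risk haplotype in near-complete LD — confers dominant, very high
risk concentrated in the early-onset subgroup. `onsetstrat` packages the full
analysis chain for this kind of study, together with a synthetic cohort
generator that reproduces its statistical structure so every stage can be
exercised and validated without access to controlled individual-level data.

## What it computes

- **Onset mixture decomposition.** Case onset ages are modelled as a
  K-component normal mixture, fitted by EM with restarts; K is chosen by
  BIC = −2 ln L + (3K−1) ln n over K = 1..7. Cases are assigned to the
  early/late subgroup when the component posterior
  w_k φ(a; μ_k, σ_k) / Σ_j w_j φ(a; μ_j, σ_j) exceeds 0.8, else left
  unassigned (`GaussianMixture1D`, `classify_subgroups`).
- **Stratified association.** Per-variant case-control tests by
  Cochran–Mantel–Haenszel analysis over per-stratum allele-count tables
  (Robins–Breslow–Greenland SE) or logistic regression with eigenvector
  covariates via an IRLS solver that reports Wald SEs, log-likelihoods, and
  flags separation; genome-wide significance at P < 5×10⁻⁸ and genomic
  inflation λ = median(χ²)/0.4549 (`cmh_allelic_test`, `association_scan`).
- **Effect-size contrasts.** Z = (ln OR₁ − ln OR₂) / √(SE₁² + SE₂²) between
  disjoint subgroups, flagged at P_Z < 5×10⁻⁵ (`effect_size_difference`).
- **Two-locus haplotype dissection.** Haplotype-frequency EM over unphased
  genotype pairs, LD statistics (D, D′, r²), conditional association
  ("same signal" when both conditional P > 0.05), additive (0/1/2) vs
  additive+dominance vs complete-dominance (0/1/1) model comparison by
  dominance-term Wald test and BIC, and BIC selection over haplotype-defining
  marker sets (`TwoLocusPhaser`, `dominance_model_comparison`).
- **Variance explained.** McFadden pseudo-r² differences between nested
  logistic models, expressed as fractions of an externally supplied total
  heritability (`variant_variance_contribution`).
- **Onset profile, comorbidity, expression.** Risk-haplotype frequency per
  1-year onset bin with exact Clopper–Pearson CIs; Fisher-exact comorbidity
  contrasts and case-only protective models; OLS genotype–expression
  regression of MFI on allele counts and allele-specific expression
  summaries (`haplotype_frequency_profile`, `fisher_exact_2x2`,
  `expression_genotype_regression`, `ase_summary`).

The model-fitting cores are scikit-learn-style estimators (`fit`,
`predict_proba`, trailing-underscore fitted attributes) and compose with
sklearn tooling; module-level functions wrap them for one-call use. A thin
CLI (`onsetstrat simulate/mixture/scan/contrast/hapmodel/run`) drives the
same library code.

## Worked example

```python
import numpy as np
from onsetstrat import (ScenarioConfig, simulate_cohort, select_components,
                        classify_subgroups, dominance_model_comparison,
                        phase_two_locus, ld_statistics)

cfg = ScenarioConfig(n_cases=1100, n_controls=10000, master_seed=1,
                     max_draws=3_000_000)
cohort = simulate_cohort(cfg)          # dominant OR 8.10 risk haplotype
ages = cohort.cases()["onset_age"].to_numpy()

fit = select_components(ages, k_max=7, restarts=10, seed=1)
assign = classify_subgroups(fit, ages, threshold=0.8)
phaser = phase_two_locus(cohort.data[["g_indel", "g_snp"]].to_numpy())
ld = ld_statistics(phaser.haplotype_table_)
comp = dominance_model_comparison(cohort.data["status"].to_numpy(float),
                                  cohort.data["hap_copies"].to_numpy(float))
```

Output (printed by the snippet above with the shown seed):

```
selected K=2; means=[12.1 37. ], sds=[ 5.6 13.2], weights=[0.412 0.588]
labels: {'late': 546, 'early': 381, 'unassigned': 173}
boundaries: {'early': (0, 16), 'late': (25, 120)}
D'=0.974, r2=0.065
winner=complete_dominance, dominance p=0.0113, carrier OR=8.38
```

Reading it: BIC picks two onset components; 381 cases exceed the 0.8
posterior for the early component (integer ages 0–16 under this cohort's
fit), 173 sit in the ambiguous middle and stay unassigned. The phasing EM
recovers the planted near-complete LD (D′ ≈ 0.97; r² is small because the
indel is rare, and higher than its population value because cases — enriched
for the risk haplotype — are over-represented in a case-control sample). The
dominance comparison detects a significant dominance term, prefers the
complete-dominance coding by BIC, and estimates the carrier OR near the
planted 8.10. The component means sit above the generating values
(10.3/34.0) because case ascertainment over-samples risk-haplotype carriers,
whose onset distribution is shifted early, and onset draws are truncated at
zero — see `docs/methods.md`.

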