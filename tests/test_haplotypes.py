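"""Two-locus phasing EM, LD statistics, conditional and dominance models."""

import numpy as np
import pandas as pd
import pytest

from onsetstrat import (ScenarioConfig, build_haplotype_table,
                        conditional_association, dominance_model_comparison,
                        haplotype_model_selection, ld_statistics,
                        phase_two_locus, simulate_cohort)
from onsetstrat.haplotypes import MonomorphicLocusError
from onsetstrat.simulate import HAPLOTYPES, HaplotypeTable


def _sample_genotypes(table, n, rng):
    h1 = rng.choice(4, n, p=table.freqs)
    h2 = rng.choice(4, n, p=table.freqs)
    g1 = np.isin(h1, (0, 1)).astype(int) + np.isin(h2, (0, 1)).astype(int)
    g2 = np.isin(h1, (0, 2)).astype(int) + np.isin(h2, (0, 2)).astype(int)
    return np.column_stack([g1, g2]), h1, h2


class TestPhasing:
    def test_double_homozygotes_counted_exactly(self):
        # genotypes 0/2 at both loci carry no phase ambiguity
        G = np.array([[0, 0]] * 30 + [[2, 2]] * 10 + [[0, 2]] * 20)
        ph = phase_two_locus(G)
        f = ph.haplotype_table_.freqs
        assert f[0] == pytest.approx(20 / 120, abs=1e-12)   # del-A
        assert f[3] == pytest.approx(60 / 120, abs=1e-12)   # TG-T
        assert f[2] == pytest.approx(40 / 120, abs=1e-12)   # TG-A

    def test_matches_direct_counting_without_double_hets(self, rng):
        table = build_haplotype_table(0.3, 0.4, 0.5)
        G, h1, h2 = _sample_genotypes(table, 500, rng)
        keep = ~((G[:, 0] == 1) & (G[:, 1] == 1))
        ph = phase_two_locus(G[keep])
        counts = np.bincount(np.r_[h1[keep], h2[keep]], minlength=4)
        assert np.allclose(ph.haplotype_table_.freqs, counts / counts.sum(),
                           atol=1e-12)

    def test_planted_frequencies_recovered(self, rng):
        table = build_haplotype_table(0.035, 0.427, 0.98)
        G, _, _ = _sample_genotypes(table, 10000, rng)
        ph = phase_two_locus(G)
        mc_se = np.sqrt(0.0346 * (1 - 0.0346) / 20000)
        assert abs(ph.haplotype_table_.freq_delA - 0.034599) < 3 * mc_se

    def test_em_loglik_monotone(self, rng):
        table = build_haplotype_table(0.2, 0.5, 0.6)
        G, _, _ = _sample_genotypes(table, 400, rng)
        ph = phase_two_locus(G)
        path = np.asarray(ph.loglik_path_)
        assert np.all(np.diff(path) >= -1e-9 * np.abs(path[:-1]))

    def test_phased_input_bypasses_em(self, small_cohort):
        haps = np.r_[small_cohort.data["hap1"].to_numpy(),
                     small_cohort.data["hap2"].to_numpy()]
        ph = phase_two_locus(phased_haplotypes=haps)
        assert ph.n_iter_ == 0
        counts = pd.Series(haps).value_counts()
        assert ph.haplotype_table_.freq_delA == pytest.approx(
            counts.get("del-A", 0) / len(haps), abs=1e-15)

    def test_diplotype_posteriors_sum_to_one(self, rng):
        table = build_haplotype_table(0.3, 0.5, 0.3)
        G, _, _ = _sample_genotypes(table, 200, rng)
        ph = phase_two_locus(G)
        post = ph.predict_proba(G)
        assert np.allclose(post["p_cis"] + post["p_trans"], 1.0)
        unambig = ~((G[:, 0] == 1) & (G[:, 1] == 1))
        assert (post.loc[unambig, "p_cis"] == 1.0).all()


class TestLD:
    def test_round_trip_identity_on_grid(self):
        for p in (0.05, 0.3, 0.5):
            for q in (0.1, 0.427, 0.8):
                for dp in (0.0, 0.4, 0.98):
                    t = build_haplotype_table(p, q, dp)
                    assert ld_statistics(t).d_prime == pytest.approx(dp, abs=1e-10)

    def test_r2_value_for_study_frequencies(self):
        t = build_haplotype_table(0.035, 0.427, 0.98)
        assert ld_statistics(t).r2 == pytest.approx(0.0467, abs=0.0005)

    def test_equilibrium_has_zero_ld(self):
        t = build_haplotype_table(0.2, 0.6, 0.0)
        s = ld_statistics(t)
        assert s.D == pytest.approx(0.0, abs=1e-15)
        assert s.r2 == pytest.approx(0.0, abs=1e-15)

    def test_monomorphic_undefined(self):
        with pytest.raises(MonomorphicLocusError):
            ld_statistics(HaplotypeTable(0.0, 0.0, 0.4, 0.6))


class TestConditional:
    def test_exact_copy_is_collinear_same_signal(self, rng):
        y = rng.binomial(1, 0.4, 200).astype(float)
        g = rng.binomial(2, 0.3, 200).astype(float)
        res = conditional_association(y, g, g.copy())
        assert res["same_signal"] is True
        assert "collinear" in res["reason"]

    def test_independent_effects_both_significant(self):
        cfg = ScenarioConfig(n_cases=700, n_controls=7000, risk_on="indel",
                             risk_model="additive", odds_ratio=3.35,
                             odds_ratio_snp=1.91, master_seed=42,
                             max_draws=2_000_000)
        c = simulate_cohort(cfg)
        df = c.data
        res = conditional_association(df["status"].to_numpy(float),
                                      df["g_indel"].to_numpy(float),
                                      df["g_snp"].to_numpy(float))
        assert res["g1"].p < 1e-4 and res["g2"].p < 1e-4
        assert res["same_signal"] is False
        assert res["g1"].ci95[0] < 3.35 < res["g1"].ci95[1]

    def test_noise_predictor_null(self, small_cohort, rng):
        df = small_cohort.data
        noise = rng.binomial(2, 0.3, len(df)).astype(float)
        res = conditional_association(df["status"].to_numpy(float),
                                      df["g_indel"].to_numpy(float), noise)
        assert res["g2"].p > 1e-3  # no systematic signal


@pytest.fixture(scope="module")
def dominant_cohort():
    cfg = ScenarioConfig(n_cases=1100, n_controls=10000, master_seed=17,
                         max_draws=3_000_000)
    return simulate_cohort(cfg)


class TestDominance:

    def test_complete_dominance_wins_under_dominant_truth(self, dominant_cohort):
        df = dominant_cohort.data
        comp = dominance_model_comparison(df["status"].to_numpy(float),
                                          df["hap_copies"].to_numpy(float))
        assert comp.winner == "complete_dominance"
        fit = comp.fit("complete_dominance")
        or_hat = np.exp(fit.coef["carrier"])
        lo = np.exp(fit.coef["carrier"] - 1.96 * fit.se["carrier"])
        hi = np.exp(fit.coef["carrier"] + 1.96 * fit.se["carrier"])
        assert lo < 8.10 < hi
        assert or_hat == pytest.approx(8.10, rel=0.25)

    def test_additive_truth_prefers_additive(self):
        wins = 0
        for s in range(5):
            cfg = ScenarioConfig(n_cases=600, n_controls=5000,
                                 risk_model="additive", odds_ratio=3.0,
                                 master_seed=200 + s, max_draws=2_000_000)
            df = simulate_cohort(cfg).data
            comp = dominance_model_comparison(df["status"].to_numpy(float),
                                              df["hap_copies"].to_numpy(float))
            wins += comp.winner == "additive"
        assert wins >= 4

    def test_bic_formula_and_single_winner(self, dominant_cohort):
        df = dominant_cohort.data
        comp = dominance_model_comparison(df["status"].to_numpy(float),
                                          df["hap_copies"].to_numpy(float))
        tab = comp.bic_table()
        assert tab["winner"].sum() == 1
        for _, row in tab.iterrows():
            assert row["bic"] == pytest.approx(
                -2 * row["loglik"] + row["k"] * np.log(len(df)), rel=1e-12)

    def test_no_homozygotes_flagged(self, rng):
        y = rng.binomial(1, 0.3, 300).astype(float)
        h = rng.binomial(1, 0.2, 300).astype(float)  # never 2 copies
        comp = dominance_model_comparison(y, h)
        assert "indistinguishable" in comp.flag

    def test_subject_reordering_invariance(self, small_cohort, rng):
        df = small_cohort.data
        y = df["status"].to_numpy(float)
        h = df["hap_copies"].to_numpy(float)
        perm = rng.permutation(len(df))
        a = dominance_model_comparison(y, h)
        b = dominance_model_comparison(y[perm], h[perm])
        assert a.winner == b.winner
        assert a.fit("additive").bic == pytest.approx(b.fit("additive").bic,
                                                      rel=1e-9)


class TestModelSelection:
    def test_focal_pair_beats_noisy_classical_marker(self):
        wins = 0
        for s in range(6):
            cfg = ScenarioConfig(n_cases=500, n_controls=3000,
                                 master_seed=300 + s, max_draws=2_000_000)
            df = simulate_cohort(cfg).data
            y = df["status"].to_numpy(float)
            sets = {
                "indel+snp": df[["g_indel", "g_snp"]],
                "indel+snp+classical": df[["g_indel", "g_snp",
                                           "classical_count"]],
                "classical+snp": df[["classical_count", "g_snp"]],
            }
            comp = haplotype_model_selection(y, sets)
            wins += comp.winner == "indel+snp"
        assert wins >= 5

    def test_single_candidate_trivially_selected(self, small_cohort):
        df = small_cohort.data
        comp = haplotype_model_selection(df["status"].to_numpy(float),
                                         {"only": df[["g_indel"]]})
        assert comp.winner == "only"

    def test_pure_noise_addition_worsens_bic(self, small_cohort, rng):
        df = small_cohort.data
        y = df["status"].to_numpy(float)
        noise = rng.standard_normal(len(df))
        comp = haplotype_model_selection(y, {
            "base": df[["g_indel", "g_snp"]],
            "base+noise": pd.concat(
                [df[["g_indel", "g_snp"]].reset_index(drop=True),
                 pd.Series(noise, name="noise")], axis=1),
        })
        assert comp.fit("base+noise").bic > comp.fit("base").bic

    def test_mismatched_subject_sets_rejected(self, small_cohort):
        df = small_cohort.data
        with pytest.raises(ValueError, match="identical subject set"):
            haplotype_model_selection(df["status"].to_numpy(float),
                                      {"bad": df[["g_indel"]].iloc[:-5]})
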