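"""Generator contracts: determinism, calibration of prevalence and liability
variance share, admixture frequencies, mortality closed forms, weight noise."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mrmort.simulate import (
    CauseHazard,
    SimulationConfig,
    SimulationError,
    TruePanel,
    simulate_cohort,
    simulate_genotypes,
    simulate_gwas_weights,
    simulate_mortality,
    simulate_panel,
    simulate_phenotypes,
)


def _fast(n, m, seed=0, **kw):
    kw.setdefault("compute_pcs", False)
    kw.setdefault("missing_dosage_rate", 0.0)
    kw.setdefault("hba1c_missing_rate", 0.0)
    return SimulationConfig(n_individuals=n, n_snps=m, seed=seed, **kw)


class TestConfigValidation:
    @pytest.mark.parametrize("kw", [
        {"n_snps": 0},
        {"n_individuals": 0},
        {"maf_range": (0.0, 0.5)},
        {"maf_range": (0.1, 0.6)},
        {"target_prevalence": 1.2},
        {"grs_liability_r2": 1.0},
        {"cause_hazards": {"x": CauseHazard(-1.0)}},
    ])
    def test_invalid_config_rejected(self, kw):
        with pytest.raises(SimulationError):
            SimulationConfig(**kw).validate()


class TestPanel:
    def test_zero_r2_gives_zero_effects(self):
        panel = simulate_panel(_fast(100, 50, grs_liability_r2=0.0))
        assert (panel.effects == 0).all()

    def test_same_seed_identical(self):
        cfg = _fast(100, 40, seed=3)
        p1, p2 = simulate_panel(cfg), simulate_panel(cfg)
        pd.testing.assert_frame_equal(p1.table, p2.table)

    def test_palindromic_flags_match_alleles(self):
        panel = simulate_panel(_fast(100, 300, seed=1))
        t = panel.table
        pal = t.apply(lambda r: {r["effect_allele"], r["other_allele"]}
                      in ({"A", "T"}, {"C", "G"}), axis=1)
        assert (pal == t["palindromic"]).all()

    def test_pathways_partition_causal_snps(self):
        panel = simulate_panel(_fast(100, 64, seed=2))
        nonzero = panel.table[panel.table["effect"] != 0]
        assert nonzero["pathway"].nunique() <= 8
        assert (nonzero["pathway"] != "").all()


class TestGenotypes:
    def test_maf_half_gives_mean_dosage_one(self):
        # symmetric frequencies: expected dosage exactly 1
        m, n = 20, 8000
        table = pd.DataFrame({
            "chrom": "1", "pos": np.arange(m), "effect_allele": "A",
            "other_allele": "G", "maf_pop1": 0.5, "maf_pop2": 0.5,
            "effect": 0.0, "pathway": "", "palindromic": False,
            "minus_strand": False,
        }, index=pd.Index([f"rs{i}" for i in range(m)], name="rsid"))
        panel = TruePanel(table=table, liability_sd=1.0)
        geno = simulate_genotypes(panel, _fast(n, m))
        mean = np.nanmean(geno.dosages.to_numpy())
        mc_se = np.sqrt(0.5 / (n * m))  # var(dosage)=2*0.25
        assert abs(mean - 1.0) < 3 * mc_se

    def test_zero_ancestry_recovers_pop2_frequency(self):
        cfg = _fast(5000, 30, seed=4, ancestry_beta=(1e-4, 50.0))
        panel = simulate_panel(cfg)
        geno = simulate_genotypes(panel, cfg)
        counted_is_eff = (geno.variants["counted_allele"]
                          == panel.table["effect_allele"]).to_numpy()
        d = np.where(counted_is_eff[None, :], geno.dosages.to_numpy(),
                     2 - geno.dosages.to_numpy())
        freq = np.nanmean(d, axis=0) / 2
        f2 = panel.table["maf_pop2"].to_numpy()
        se = np.sqrt(f2 * (1 - f2) / (2 * 5000))
        assert np.all(np.abs(freq - f2) < 4 * se + 1e-3)

    def test_allele_frequency_binomial_oracle(self):
        # empirical effect-allele frequency vs the analytic mixed frequency,
        # judged against an exact binomial interval per SNP
        n = 20_000
        cfg = _fast(n, 40, seed=5)
        panel = simulate_panel(cfg)
        geno = simulate_genotypes(panel, cfg)
        a, b = cfg.ancestry_beta
        abar = a / (a + b)
        fbar = (abar * panel.table["maf_pop1"]
                + (1 - abar) * panel.table["maf_pop2"]).to_numpy()
        counted_is_eff = (geno.variants["counted_allele"]
                          == panel.table["effect_allele"]).to_numpy()
        d = np.where(counted_is_eff[None, :], geno.dosages.to_numpy(),
                     2 - geno.dosages.to_numpy())
        counts = np.nansum(d, axis=0).astype(int)
        # 2n allele draws per SNP; admixture widens the spread, so use the
        # exact binomial band at a conservative level
        lo, hi = stats.binom.interval(1 - 1e-6 / 40, 2 * n, fbar)
        assert np.all((counts >= lo - 2 * n * 0.01) & (counts <= hi + 2 * n * 0.01))

    def test_missingness_rate(self):
        cfg = _fast(2000, 50, missing_dosage_rate=0.05, seed=6)
        panel = simulate_panel(cfg)
        geno = simulate_genotypes(panel, cfg)
        frac = geno.dosages.isna().to_numpy().mean()
        assert abs(frac - 0.05) < 0.005


class TestPhenotypes:
    def test_prevalence_calibration(self):
        cfg = _fast(50_000, 100, seed=8)
        panel = simulate_panel(cfg)
        geno = simulate_genotypes(panel, cfg)
        ppl = simulate_phenotypes(geno, panel, cfg)
        assert abs(ppl["t2d_true"].mean() - 0.18) < 0.01

    def test_liability_variance_share(self):
        # direct variance computation on the simulated liabilities
        cfg = _fast(50_000, 100, seed=9)
        panel = simulate_panel(cfg)
        geno = simulate_genotypes(panel, cfg)
        ppl = simulate_phenotypes(geno, panel, cfg)
        share = ppl["grs_true"].var() / ppl["liability"].var()
        assert abs(share - 0.06) < 0.01

    def test_confounder_independence_from_grs(self):
        cfg = _fast(20_000, 60, seed=10)
        panel = simulate_panel(cfg)
        geno = simulate_genotypes(panel, cfg)
        ppl = simulate_phenotypes(geno, panel, cfg)
        smoker = (ppl["smoking"].str.startswith("current")).astype(float)
        r = np.corrcoef(smoker, ppl["grs_true"])[0, 1]
        assert abs(r) < 3 / np.sqrt(len(ppl))

    def test_infinite_noise_limit_kills_signal(self):
        # r2 -> 0 approximates liability noise -> infinity: GRS-T2D odds
        # ratio tends to 1
        cfg = _fast(20_000, 60, seed=11, grs_liability_r2=1e-6)
        panel = simulate_panel(cfg)
        geno = simulate_genotypes(panel, cfg)
        ppl = simulate_phenotypes(geno, panel, cfg)
        from mrmort.survival import fit_logistic
        est = fit_logistic(ppl["t2d_true"].astype(float), ppl["grs_true"])
        # log OR per SD of the score
        assert abs(est.beta * ppl["grs_true"].std()) < 0.05

    def test_undiagnosed_hba1c_clears_threshold(self, small_cohort):
        ppl = small_cohort.participants
        undiag = ppl["t2d_true"] & ~ppl["self_reported_diabetes"]
        assert (ppl.loc[undiag, "hba1c"] >= 6.5).all()


class TestMortality:
    def test_zero_rates_no_deaths(self, small_cohort):
        cfg = _fast(0, 0)
        cfg = SimulationConfig(
            n_individuals=3000, n_snps=60, seed=7,
            cause_hazards={"cardiac": CauseHazard(0.0, 0.0)})
        fu = simulate_mortality(small_cohort.participants, cfg)
        assert not fu["died"].any()

    def test_exponential_closed_form(self):
        # single cause, no T2D effect: deaths ~ Binomial(n, 1 - exp(-rT))
        n, r, T = 30_000, 0.004, 20.0
        cfg = _fast(n, 10, seed=12,
                    cause_hazards={"cardiac": CauseHazard(r, 0.0)})
        panel = simulate_panel(cfg)
        geno = simulate_genotypes(panel, cfg)
        ppl = simulate_phenotypes(geno, panel, cfg)
        fu = simulate_mortality(ppl, cfg)
        p = 1 - np.exp(-r * T)
        lo, hi = stats.binom.interval(0.9999, n, p)
        assert lo <= fu["died"].sum() <= hi

    def test_crude_rate_ratio_recovers_planted_effect(self):
        n = 50_000
        cfg = _fast(n, 50, seed=13,
                    cause_hazards={"renal": CauseHazard(0.003, np.log(2.0))})
        panel = simulate_panel(cfg)
        geno = simulate_genotypes(panel, cfg)
        ppl = simulate_phenotypes(geno, panel, cfg)
        fu = simulate_mortality(ppl, cfg)
        t2d = ppl["t2d_true"].to_numpy()
        py = fu["exit_age"] - fu["entry_age"]
        rate1 = fu["died"][t2d].sum() / py[t2d].sum()
        rate0 = fu["died"][~t2d].sum() / py[~t2d].sum()
        rr = rate1 / rate0
        se_log = np.sqrt(1 / fu["died"][t2d].sum() + 1 / fu["died"][~t2d].sum())
        assert abs(np.log(rr) - np.log(2)) < 3 * se_log

    def test_competing_risks_accounting(self, small_cohort):
        fu = small_cohort.followup
        died = fu["died"]
        assert (fu.loc[died, "true_cause_group"] != "").all()
        assert (fu.loc[~died, "true_cause_group"] == "").all()
        assert fu.loc[died, "true_cause_group"].value_counts().sum() == died.sum()
        assert (fu["exit_age"] > fu["entry_age"]).all()

    def test_miscoding_only_in_t2d_deaths(self, small_cohort):
        fu, ppl = small_cohort.followup, small_cohort.participants
        miscoded = fu["underlying_cause_icd10"] == "E11.9"
        assert miscoded.any()
        assert ppl.loc[miscoded, "t2d_true"].all()
        # true cause retained as a secondary code
        assert (fu.loc[miscoded, "secondary_causes"] != "").all()


class TestWeights:
    def test_zero_noise_weights_proportional_to_truth(self):
        cfg = _fast(100, 80, seed=14, weight_true_corr=1.0)
        panel = simulate_panel(cfg)
        w = simulate_gwas_weights(panel, cfg)
        expected = panel.effects * cfg.liability_logodds_scale / panel.liability_sd
        np.testing.assert_allclose(w["weight"].to_numpy(), expected, atol=1e-12)

    def test_huge_noise_kills_correlation(self):
        cfg = _fast(100, 1000, seed=15, weight_true_corr=0.02)
        panel = simulate_panel(cfg)
        w = simulate_gwas_weights(panel, cfg)
        r = np.corrcoef(panel.effects, w["weight"])[0, 1]
        assert abs(r) < 0.1

    def test_attenuation_formula_oracle(self):
        # corr(true, weight) should match sd / sqrt(sd^2 + se^2)
        cfg = _fast(100, 1000, seed=16, weight_true_corr=0.5)
        panel = simulate_panel(cfg)
        w = simulate_gwas_weights(panel, cfg)
        r = np.corrcoef(
            panel.effects * cfg.liability_logodds_scale / panel.liability_sd,
            w["weight"])[0, 1]
        assert abs(r - 0.5) < 0.1


class TestDeterminism:
    def test_full_cohort_reproducible(self):
        cfg = _fast(500, 30, seed=17)
        c1, c2 = simulate_cohort(cfg), simulate_cohort(cfg)
        pd.testing.assert_frame_equal(c1.participants, c2.participants)
        pd.testing.assert_frame_equal(c1.followup, c2.followup)
        pd.testing.assert_frame_equal(c1.genotypes.dosages, c2.genotypes.dosages)
        pd.testing.assert_frame_equal(c1.weights, c2.weights)
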