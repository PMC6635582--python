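import math

import numpy as np
import pytest

from bwmr.estimators import ivw
from bwmr.maternal import (
    MaternalBiasConfig,
    _logistic_gwas,
    genetic_score_adjust,
    maternal_bias,
    maternal_bias_mc,
    maternal_confounding_sim,
)
from bwmr.summary_io import HarmonizedInstrument
from bwmr.synthetic import SimulationConfig, simulate_mother_child


def base_config(**kw):
    defaults = dict(
        n_snps=10, theta=math.log(1.34), n_exposure=50_000, n_outcome=20_000,
        case_fraction=0.33, seed=7, pve_per_snp=0.01,
    )
    defaults.update(kw)
    return SimulationConfig(**defaults)


class TestClosedForm:
    def test_published_anchor_evaluations(self):
        assert maternal_bias(0.30, 0.069) == pytest.approx(7.87, abs=0.005)
        assert maternal_bias(0.30, 0.28) == pytest.approx(2.16, abs=0.005)

    def test_accepts_config_object(self):
        assert maternal_bias(MaternalBiasConfig(0.30, 0.069)) == pytest.approx(7.87, abs=0.005)

    def test_vanishes_without_maternal_effect(self):
        for pi in (0.01, 0.069, 0.28, 0.45):
            assert maternal_bias(0.0, pi) == 0.0

    def test_increasing_in_effect_magnitude(self):
        grid = [maternal_bias(v, 0.069) for v in (0.05, 0.1, 0.2, 0.3, 0.4)]
        assert all(a < b for a, b in zip(grid, grid[1:]))
        assert maternal_bias(-0.3, 0.069) == maternal_bias(0.3, 0.069)

    def test_decreasing_in_lbw_probability(self):
        grid = [maternal_bias(0.3, p) for p in (0.02, 0.069, 0.15, 0.28, 0.4)]
        assert all(a > b for a, b in zip(grid, grid[1:]))

    def test_continuity_near_anchor(self):
        assert maternal_bias(0.3, 0.0691) == pytest.approx(maternal_bias(0.3, 0.069), rel=0.01)

    @pytest.mark.parametrize("pi", [0.0, 1.0, -0.1, 1.5])
    def test_pi_domain_errors(self, pi):
        with pytest.raises(ValueError):
            maternal_bias(0.3, pi)


class TestMonteCarloFallback:
    def test_zero_effect_gives_zero_bias(self):
        assert maternal_bias_mc(0.0, 0.069, n_individuals=50_000, seed=0) == pytest.approx(0.0, abs=1e-9)

    def test_direction_and_order_agree_at_low_prevalence(self):
        """At the developed-country anchor the mechanism reproduces the
        closed form's sign and order of magnitude (a few percent upward)."""
        mc = maternal_bias_mc(0.30, 0.069, n_individuals=400_000, seed=3)
        closed = maternal_bias(0.30, 0.069)
        assert mc > 0
        assert closed / 10 < mc < closed * 10

    def test_same_order_of_magnitude_at_high_prevalence(self):
        mc = maternal_bias_mc(0.30, 0.28, n_individuals=400_000, seed=3)
        assert abs(mc) < 10 * maternal_bias(0.30, 0.28) + 1


class TestVectorizedLogisticGwas:
    def test_matches_statsmodels_logit(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(0)
        G = rng.binomial(2, 0.3, size=(4000, 3)).astype(float)
        eta = -0.6 + 0.12 * G[:, 1] - 0.2 * G[:, 2]
        d = rng.binomial(1, 1 / (1 + np.exp(-eta)))
        b, se = _logistic_gwas(G, d)
        for j in range(3):
            fit = sm.Logit(d, sm.add_constant(G[:, j])).fit(disp=0)
            assert b[j] == pytest.approx(fit.params[1], abs=1e-8)
            assert se[j] == pytest.approx(fit.bse[1], rel=1e-6)


class TestMotherChildCohort:
    def test_genotype_correlation_is_half(self):
        cohort = simulate_mother_child(base_config(n_snps=5), 50_000)
        assert np.allclose(cohort.genotype_correlations(), 0.5, atol=0.02)

    def test_child_allele_frequency_conserved(self):
        cohort = simulate_mother_child(base_config(n_snps=5, seed=9), 50_000)
        freq = cohort.child_genotypes.mean(axis=0) / 2.0
        assert np.allclose(freq, cohort.maf, atol=0.01)

    def test_instrument_variance_accounting(self):
        cfg = base_config(n_snps=8, seed=3)
        cohort = simulate_mother_child(cfg, 100_000)
        fetal = (cohort.child_genotypes - 2 * cohort.maf) @ cohort.gamma
        explained = fetal.var() / cohort.birth_weight.var()
        total_pve = float(np.sum(cfg.pve_vector()))
        assert explained == pytest.approx(total_pve, abs=3 * 0.01)

    def test_infeasible_variance_budget_rejected(self):
        # the config itself guards the fetal variance budget
        with pytest.raises(ValueError, match="PVE"):
            base_config(n_snps=10, pve_per_snp=0.11)


class TestGeneticScoreAdjustment:
    def test_null_disease_calibration(self):
        """Disease independent of both scores: adjusted OR near 1 and the CI
        covers 1 at close to the nominal rate."""
        rng = np.random.default_rng(15)
        covered = 0
        reps = 40
        for r in range(reps):
            cfg = base_config(n_snps=6, theta=0.0, seed=int(rng.integers(2**31 - 1)))
            cohort = simulate_mother_child(cfg, 4_000)
            res = genetic_score_adjust(cohort, cohort.gamma, cohort.gamma)
            covered += res.ci_low <= 1.0 <= res.ci_high
        assert covered >= int(0.85 * reps)

    def test_zero_maternal_path_leaves_estimate_unchanged(self):
        cfg = base_config(n_snps=6, seed=31, maternal_pve_per_snp=0.0)
        cohort = simulate_mother_child(cfg, 30_000)
        adj = genetic_score_adjust(cohort, cohort.gamma, cohort.gamma)
        unadj = genetic_score_adjust(cohort, cohort.gamma, adjust_maternal=False)
        assert adj.beta == pytest.approx(unadj.beta, abs=3 * math.hypot(adj.se, unadj.se))

    def test_adjustment_reduces_bias_under_maternal_path(self):
        """With a direct maternal-score path to disease, controlling for the
        maternal score moves the offspring-score estimate toward its truth."""
        rng = np.random.default_rng(99)
        err_adj, err_unadj = [], []
        for r in range(30):
            cfg = base_config(
                n_snps=6, seed=int(rng.integers(2**31 - 1)),
                maternal_pve_per_snp=0.01, maternal_direct_effect=0.5,
                maternal_fetal_sign_concordance=1.0,
            )
            cohort = simulate_mother_child(cfg, 8_000)
            weights = cohort.gamma
            adj = genetic_score_adjust(cohort, weights, cohort.vartheta)
            unadj = genetic_score_adjust(cohort, weights, adjust_maternal=False)
            # truth: log-odds per offspring-score SD from the generative model
            score = (cohort.child_genotypes - 2 * cohort.maf) @ weights
            truth = cfg.theta * score.std()
            err_adj.append(abs(adj.beta - truth))
            err_unadj.append(abs(unadj.beta - truth))
        assert np.mean(err_adj) < np.mean(err_unadj)

    def test_misaligned_weights_rejected(self):
        cohort = simulate_mother_child(base_config(n_snps=4), 500)
        with pytest.raises(ValueError, match="align"):
            genetic_score_adjust(cohort, [0.1, 0.2])


class TestConfoundingSimulation:
    def test_requires_zero_level_and_valid_theta(self):
        cfg = base_config()
        with pytest.raises(ValueError, match="include 0"):
            maternal_confounding_sim(cfg, [0.001], n_reps=2, seed=0)
        with pytest.raises(ValueError):
            maternal_confounding_sim(base_config(theta=0.0), [0.0], n_reps=2, seed=0)

    def test_reproducible_given_seed(self):
        cfg = base_config(n_snps=4)
        a = maternal_confounding_sim(cfg, [0.0, 0.01], n_reps=4, seed=5, n_cohort=4_000)
        b = maternal_confounding_sim(cfg, [0.0, 0.01], n_reps=4, seed=5, n_cohort=4_000)
        assert a.equals(b)

    def test_null_level_unbiased_and_strong_level_upward(self):
        # full sign concordance isolates the confounding signal at small reps
        cfg = base_config(maternal_fetal_sign_concordance=1.0)
        table = maternal_confounding_sim(cfg, [0.0, 0.1], n_reps=15, seed=11, n_cohort=20_000)
        null_row = table[table.maternal_pve == 0.0].iloc[0]
        strong_row = table[table.maternal_pve == 0.1].iloc[0]
        assert abs(null_row.mean_bias) < 3 * null_row.mc_se
        assert strong_row.mean_bias > 3 * strong_row.mc_se

    def test_excluding_maternal_instruments_reduces_bias(self):
        """Dropping the instruments that carry maternal effects (the
        instrument-exclusion sensitivity strategy) shrinks the bias of the
        IVW estimate under maternal confounding."""
        rng = np.random.default_rng(2024)
        theta = math.log(1.34)
        mpve = np.array([0.05] * 5 + [0.0] * 5)
        bias_full, bias_clean = [], []
        for r in range(25):
            cfg = base_config(
                seed=int(rng.integers(2**31 - 1)),
                maternal_pve_per_snp=mpve,
                maternal_fetal_sign_concordance=1.0,
            )
            sub_rng = np.random.default_rng(cfg.seed)
            cohort = simulate_mother_child(cfg, 20_000, rng=sub_rng)
            from bwmr.maternal import _cohort_outcome_summaries

            het = 2.0 * cohort.maf * (1.0 - cohort.maf)
            sigma_x = 1.0 / np.sqrt(cfg.n_exposure * het)
            gamma_hat = sub_rng.normal(cohort.gamma, sigma_x)
            Gamma_hat, sigma_y = _cohort_outcome_summaries(cohort)
            ins = [
                HarmonizedInstrument(cohort.snp_ids[j], gamma_hat[j], sigma_x[j], Gamma_hat[j], sigma_y[j])
                for j in range(10)
            ]
            bias_full.append(ivw(ins).beta_hat - theta)
            bias_clean.append(ivw(ins[5:]).beta_hat - theta)
        assert abs(np.mean(bias_clean)) < abs(np.mean(bias_full))
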