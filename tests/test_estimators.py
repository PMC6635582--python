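import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bwmr.estimators import (
    cochran_q,
    egger,
    ivw,
    to_or_per_sd_decrease,
    wald_ratio,
    weighted_median,
)
from bwmr.summary_io import HarmonizedInstrument
from .conftest import random_instruments


def H(snp, g, sx, G, sy):
    return HarmonizedInstrument(snp, g, sx, G, sy)


def wls_origin_oracle(g, sy, G):
    """Zero-intercept WLS via explicit normal equations on the whitened design."""
    X = (g / sy)[:, None]
    y = G / sy
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    return float(beta[0])


def wls_intercept_oracle(g, sy, G):
    """WLS with intercept via normal equations; returns (intercept, slope, ses)
    with multiplicative dispersion floored at 1."""
    w = 1.0 / sy**2
    X = np.column_stack([np.ones_like(g), g])
    XtW = X.T * w
    cov_unscaled = np.linalg.inv(XtW @ X)
    beta = cov_unscaled @ (XtW @ G)
    resid = G - X @ beta
    scale = float(np.sum(w * resid**2) / (len(g) - 2))
    se = np.sqrt(np.diag(cov_unscaled) * max(1.0, scale))
    return beta, se


class TestWaldRatio:
    def test_direct_arithmetic(self):
        beta, se = wald_ratio(H("rs1", 0.05, 0.01, 0.10, 0.02))
        assert (beta, se) == (2.0, pytest.approx(0.4))

    def test_zero_numerator(self):
        beta, se = wald_ratio(H("rs1", 0.05, 0.01, 0.0, 0.02))
        assert beta == 0.0 and se == pytest.approx(0.4)

    def test_joint_sign_flip_leaves_ratio_unchanged(self):
        a = wald_ratio(H("rs1", 0.05, 0.01, 0.10, 0.02))
        b = wald_ratio(H("rs1", -0.05, 0.01, -0.10, 0.02))
        assert a == b

    def test_zero_gamma_rejected(self):
        with pytest.raises(ZeroDivisionError):
            wald_ratio(H("rs1", 0.0, 0.01, 0.1, 0.02))


class TestIvw:
    def test_single_instrument_reduces_to_wald(self):
        h = H("rs1", 0.05, 0.01, 0.10, 0.02)
        with pytest.warns(UserWarning):
            est = ivw([h], mode="random")
        wald_beta, wald_se = wald_ratio(h)
        assert est.beta_hat == wald_beta and est.se == wald_se
        assert est.q_stat is None

    def test_homogeneous_ratios_have_zero_q(self):
        ins = [H(f"rs{j}", g, 0.01, 2.0 * g, 0.02) for j, g in enumerate([0.04, 0.05, 0.08])]
        fixed = ivw(ins, mode="fixed")
        random = ivw(ins, mode="random")
        assert fixed.beta_hat == pytest.approx(2.0, abs=1e-12)
        assert fixed.q_stat == pytest.approx(0.0, abs=1e-18)
        assert fixed.se == random.se  # dispersion floored at 1

    def test_fixed_and_random_share_point_estimate(self, instrument_factory):
        ins = instrument_factory(np.random.default_rng(7), J=12)
        fixed, random = ivw(ins, "fixed"), ivw(ins, "random")
        assert fixed.beta_hat == random.beta_hat
        assert random.se >= fixed.se

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_weighted_regression_through_origin(self, seed, instrument_factory):
        ins = instrument_factory(np.random.default_rng(seed), J=10)
        g = np.array([h.gamma for h in ins])
        sy = np.array([h.sigma_y for h in ins])
        G = np.array([h.Gamma_out for h in ins])
        assert ivw(ins).beta_hat == pytest.approx(wls_origin_oracle(g, sy, G), abs=1e-8)

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            ivw([])


class TestCochranQ:
    def test_homogeneous_ratios(self):
        ins = [H(f"rs{j}", 0.05, 0.01, 0.1, 0.02) for j in range(4)]
        q, qp, i2 = cochran_q(ins, 2.0)
        assert q == pytest.approx(0.0, abs=1e-18)
        assert i2 == 0.0

    def test_hand_arithmetic_two_instruments(self):
        # unit weights (gamma = sigma_y = 1), ratios {0, 2}, beta_hat = 1
        ins = [H("a", 1.0, 0.1, 0.0, 1.0), H("b", 1.0, 0.1, 2.0, 1.0)]
        q, qp, i2 = cochran_q(ins, 1.0)
        assert q == pytest.approx(2.0)
        assert i2 == pytest.approx(0.5)

    def test_requires_two_instruments(self):
        with pytest.raises(ValueError):
            cochran_q([H("a", 1.0, 0.1, 0.0, 1.0)], 0.0)


class TestWeightedMedian:
    def test_equal_weights_middle_order_statistic(self):
        ins = [H(f"rs{j}", 1.0, 0.01, r, 1.0) for j, r in enumerate([1.0, 2.0, 9.0])]
        assert weighted_median(ins, n_boot=10, seed=0).beta_hat == 2.0

    def test_identical_ratios_recovered_with_small_se(self):
        ins = [H(f"rs{j}", g, 0.001, 1.7 * g, 0.001) for j, g in enumerate([0.05, 0.08, 0.1, 0.2])]
        est = weighted_median(ins, n_boot=200, seed=1)
        assert est.beta_hat == pytest.approx(1.7, abs=1e-12)
        assert est.se < 0.15

    @given(st.lists(st.floats(-5, 5), min_size=3, max_size=9).filter(lambda v: len(v) % 2 == 1))
    @settings(max_examples=50, deadline=None)
    def test_equal_weights_odd_j_equals_sample_median(self, ratios):
        ins = [H(f"rs{j}", 1.0, 0.01, r, 1.0) for j, r in enumerate(ratios)]
        est = weighted_median(ins, n_boot=2, seed=0)
        assert est.beta_hat == pytest.approx(float(np.median(ratios)), abs=1e-12)

    def test_five_instrument_weighted_case_matches_enumeration_oracle(self):
        rng = np.random.default_rng(3)
        ins = random_instruments(rng, J=5)
        est = weighted_median(ins, n_boot=2, seed=0)

        # oracle: explicit cumulative-weight scan
        g = np.array([h.gamma for h in ins])
        sy = np.array([h.sigma_y for h in ins])
        ratios = np.array([h.Gamma_out for h in ins]) / g
        w = g**2 / sy**2
        order = np.argsort(ratios)
        r, p = ratios[order], w[order] / w.sum()
        s = np.cumsum(p) - 0.5 * p
        k = int(np.searchsorted(s, 0.5))
        expected = r[k - 1] + (r[k] - r[k - 1]) * (0.5 - s[k - 1]) / (s[k] - s[k - 1])
        assert est.beta_hat == pytest.approx(expected, abs=1e-12)

    def test_requires_three_instruments(self):
        with pytest.raises(ValueError):
            weighted_median([H("a", 1, 0.1, 1, 1), H("b", 1, 0.1, 2, 1)], n_boot=10, seed=0)


class TestEgger:
    def test_noiseless_line_through_origin(self):
        g = np.array([0.03, 0.05, 0.08, 0.12])
        ins = [H(f"rs{j}", gj, 0.01, 0.4 * gj, 0.02) for j, gj in enumerate(g)]
        res = egger(ins)
        assert res.slope.beta_hat == pytest.approx(0.4, abs=1e-10)
        assert res.intercept == pytest.approx(0.0, abs=1e-10)

    def test_noiseless_affine_line(self):
        g = np.array([0.03, 0.05, 0.08, 0.12])
        ins = [H(f"rs{j}", gj, 0.01, 0.01 + 0.4 * gj, 0.02) for j, gj in enumerate(g)]
        res = egger(ins)
        assert res.intercept == pytest.approx(0.01, abs=1e-10)
        assert res.slope.beta_hat == pytest.approx(0.4, abs=1e-10)

    def test_orientation_invariance(self):
        g = np.array([0.03, -0.05, 0.08, -0.12])
        rng = np.random.default_rng(0)
        G = 0.01 * np.sign(g) + 0.4 * g + rng.normal(0, 0.005, 4)
        ins = [H(f"rs{j}", g[j], 0.01, G[j], 0.02) for j in range(4)]
        flipped = [H(f"rs{j}", -g[j], 0.01, -G[j], 0.02) for j in range(4)]
        assert egger(ins).slope.beta_hat == pytest.approx(egger(flipped).slope.beta_hat)
        assert egger(ins).intercept == pytest.approx(egger(flipped).intercept)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_normal_equations_oracle(self, seed):
        ins = random_instruments(np.random.default_rng(100 + seed), J=12)
        # orient as the implementation does
        g = np.array([h.gamma for h in ins])
        flip = np.sign(g)
        go = g * flip
        G = np.array([h.Gamma_out for h in ins]) * flip
        sy = np.array([h.sigma_y for h in ins])
        beta, se = wls_intercept_oracle(go, sy, G)
        res = egger(ins)
        assert res.intercept == pytest.approx(beta[0], abs=1e-8)
        assert res.slope.beta_hat == pytest.approx(beta[1], abs=1e-8)
        assert res.intercept_se == pytest.approx(se[0], rel=1e-8)
        assert res.slope.se == pytest.approx(se[1], rel=1e-8)

    def test_degenerate_design_rejected(self):
        ins = [H(f"rs{j}", 0.05, 0.01, 0.1, 0.02) for j in range(4)]
        with pytest.raises(np.linalg.LinAlgError):
            egger(ins)

    def test_requires_three_instruments(self):
        with pytest.raises(ValueError):
            egger([H("a", 0.05, 0.01, 0.1, 0.02), H("b", 0.08, 0.01, 0.2, 0.02)])


class TestOrReporting:
    def test_published_cad_example(self):
        from bwmr.estimators import _normal_estimate

        est = _normal_estimate("ivw_random", -0.2927, 0.0683, 47)
        res = to_or_per_sd_decrease(est)
        assert res.or_per_sd_decrease == pytest.approx(1.34, abs=0.005)
        assert res.ci_low == pytest.approx(1.17, abs=0.005)
        assert res.ci_high == pytest.approx(1.53, abs=0.005)

    def test_null_effect_maps_to_unit_or(self):
        from bwmr.estimators import _normal_estimate

        res = to_or_per_sd_decrease(_normal_estimate("ivw_fixed", 0.0, 0.1, 5))
        assert res.or_per_sd_decrease == 1.0
        assert res.ci_low < 1.0 < res.ci_high

    def test_negated_estimate_gives_reciprocal_or(self):
        from bwmr.estimators import _normal_estimate

        a = to_or_per_sd_decrease(_normal_estimate("m", -0.3, 0.05, 5))
        b = to_or_per_sd_decrease(_normal_estimate("m", 0.3, 0.05, 5))
        assert a.or_per_sd_decrease == pytest.approx(1 / b.or_per_sd_decrease)
        assert a.ci_low == pytest.approx(1 / b.ci_high)
        assert a.ci_high == pytest.approx(1 / b.ci_low)
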