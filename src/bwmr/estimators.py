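"""Core causal-effect estimators on harmonized instruments.

Given J harmonized instruments (gamma_j, sigma_xj) on the exposure and
(Gamma_j, sigma_yj) on the outcome, the per-SNP Wald ratio Gamma_j / gamma_j
estimates the causal effect theta; the inverse-variance-weighted (IVW)
estimator pools the ratios with first-order weights w_j = gamma_j^2 /
sigma_yj^2, which is identical to weighted least squares of Gamma on gamma
through the origin.  Heterogeneity across ratios is measured by Cochran's Q
and I^2; the random-effects IVW inflates the fixed-effect SE by the
multiplicative overdispersion factor max(1, sqrt(Q/(J-1))).  The weighted
median is consistent when instruments carrying at least half the weight are
valid; MR-Egger adds an intercept to the weighted regression, estimating
directional pleiotropy.  For binary outcomes results are reported as odds
ratios per one SD *decrease* of the exposure, the convention of studies of
low birth weight.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import statsmodels.api as sm
from scipy.stats import chi2, norm

from .summary_io import HarmonizedInstrument

__all__ = [
    "MrEstimate",
    "EggerResult",
    "OrResult",
    "wald_ratio",
    "ivw",
    "cochran_q",
    "weighted_median",
    "egger",
    "to_or_per_sd_decrease",
    "estimates_to_frame",
]

Z95 = norm.ppf(0.975)


@dataclass(frozen=True)
class MrEstimate:
    """A causal-effect estimate with normal-theory inference attached.

    ``beta_hat`` is per 1 SD increase of the exposure, on the outcome's
    log-odds scale for binary outcomes.  Heterogeneity fields are ``None``
    when undefined (J < 2).
    """

    method: str
    beta_hat: float
    se: float
    ci_low: float
    ci_high: float
    pval: float
    n_snps: int
    q_stat: float | None = None
    q_pval: float | None = None
    i2: float | None = None

    def __post_init__(self) -> None:
        if self.se <= 0:
            raise ValueError("se must be positive")
        if not self.ci_low <= self.beta_hat <= self.ci_high:
            raise ValueError("confidence interval must bracket the estimate")
        if self.i2 is not None and not 0.0 <= self.i2 <= 1.0:
            raise ValueError("I^2 must lie in [0, 1]")


@dataclass(frozen=True)
class EggerResult:
    slope: MrEstimate
    intercept: float
    intercept_se: float
    intercept_pval: float


@dataclass(frozen=True)
class OrResult:
    or_per_sd_decrease: float
    ci_low: float
    ci_high: float


def _normal_estimate(method: str, beta: float, se: float, n_snps: int, **extra) -> MrEstimate:
    return MrEstimate(
        method=method,
        beta_hat=float(beta),
        se=float(se),
        ci_low=float(beta - Z95 * se),
        ci_high=float(beta + Z95 * se),
        pval=float(2.0 * norm.sf(abs(beta) / se)),
        n_snps=n_snps,
        **extra,
    )


def _arrays(instruments: Sequence[HarmonizedInstrument]):
    g = np.array([h.gamma for h in instruments], dtype=float)
    sx = np.array([h.sigma_x for h in instruments], dtype=float)
    G = np.array([h.Gamma_out for h in instruments], dtype=float)
    sy = np.array([h.sigma_y for h in instruments], dtype=float)
    return g, sx, G, sy


def wald_ratio(h: HarmonizedInstrument) -> tuple[float, float]:
    """Single-SNP causal estimate Gamma/gamma with first-order SE sigma_y/|gamma|."""
    if h.gamma == 0:
        raise ZeroDivisionError(f"{h.snp_id}: undefined Wald ratio (gamma = 0)")
    return h.Gamma_out / h.gamma, h.sigma_y / abs(h.gamma)


def ivw(instruments: Sequence[HarmonizedInstrument], mode: str = "random") -> MrEstimate:
    """Inverse-variance-weighted estimate across instruments.

    ``mode="fixed"`` uses SE = (sum w)^(-1/2); ``mode="random"`` applies the
    multiplicative overdispersion model, inflating the fixed SE by
    max(1, sqrt(Q/(J-1))).  Point estimates are identical in both modes.
    """
    if mode not in ("fixed", "random"):
        raise ValueError(f"unknown IVW mode {mode!r}")
    if len(instruments) == 0:
        raise ValueError("ivw requires at least one instrument")
    g, _, G, sy = _arrays(instruments)
    if np.any(g == 0):
        raise ZeroDivisionError("ivw requires gamma != 0 for every instrument")
    J = len(instruments)
    w = g * g / (sy * sy)
    ratios = G / g
    beta = float(np.sum(w * ratios) / np.sum(w))
    se_fixed = float(np.sum(w) ** -0.5)

    if J >= 2:
        q, q_pval, i2 = cochran_q(instruments, beta)
    else:
        q = q_pval = i2 = None
        if mode == "random":
            warnings.warn("random-effects IVW with a single instrument falls back to fixed", stacklevel=2)
            mode = "fixed"

    se = se_fixed
    if mode == "random" and J >= 2:
        se = se_fixed * max(1.0, math.sqrt(q / (J - 1)))
    return _normal_estimate(
        f"ivw_{mode}", beta, se, J, q_stat=q, q_pval=q_pval, i2=i2
    )


def cochran_q(
    instruments: Sequence[HarmonizedInstrument], beta_hat: float
) -> tuple[float, float, float]:
    """Cochran's Q around ``beta_hat`` with first-order IVW weights.

    Returns (Q, p from chi-square with J-1 df, I^2 = max(0, (Q-(J-1))/Q)).
    """
    J = len(instruments)
    if J < 2:
        raise ValueError("Q requires at least two instruments")
    g, _, G, sy = _arrays(instruments)
    w = g * g / (sy * sy)
    ratios = G / g
    q = float(np.sum(w * (ratios - beta_hat) ** 2))
    q_pval = float(chi2.sf(q, J - 1))
    i2 = float(max(0.0, (q - (J - 1)) / q)) if q > 0 else 0.0
    return q, q_pval, i2


def _weighted_median_point(ratios: np.ndarray, weights: np.ndarray) -> float:
    """Weighted median by linear interpolation of the cumulative weight at 1/2."""
    order = np.argsort(ratios)
    r = ratios[order]
    p = weights[order] / np.sum(weights)
    # midpoint cumulative weights: s_j = cumsum(p) - p/2
    s = np.cumsum(p) - 0.5 * p
    if 0.5 <= s[0]:
        return float(r[0])
    if 0.5 >= s[-1]:
        return float(r[-1])
    return float(np.interp(0.5, s, r))


def weighted_median(
    instruments: Sequence[HarmonizedInstrument],
    n_boot: int = 1000,
    seed: int | np.random.Generator = 0,
) -> MrEstimate:
    """Weighted-median causal estimate with parametric-bootstrap SE.

    The point estimate is the ratio value at cumulative IVW weight one half
    (interpolated between order statistics).  The SE is the standard
    deviation of the estimate across ``n_boot`` resamples drawing
    gamma* ~ N(gamma, sigma_x^2) and Gamma* ~ N(Gamma, sigma_y^2).
    """
    J = len(instruments)
    if J < 3:
        raise ValueError("weighted median requires at least three instruments")
    if n_boot < 2:
        raise ValueError("n_boot must be at least 2")
    rng = np.random.default_rng(seed)
    g, sx, G, sy = _arrays(instruments)
    if np.any(g == 0):
        raise ZeroDivisionError("weighted median requires gamma != 0")
    w = g * g / (sy * sy)
    beta = _weighted_median_point(G / g, w)

    gs = rng.normal(g, sx, size=(n_boot, J))
    Gs = rng.normal(G, sy, size=(n_boot, J))
    boots = np.empty(n_boot)
    for b in range(n_boot):
        gb = gs[b]
        gb = np.where(gb == 0, np.finfo(float).tiny, gb)
        boots[b] = _weighted_median_point(Gs[b] / gb, gb * gb / (sy * sy))
    se = float(np.std(boots, ddof=1))
    se = max(se, np.finfo(float).tiny)
    return _normal_estimate("weighted_median", beta, se, J)


def egger(instruments: Sequence[HarmonizedInstrument]) -> EggerResult:
    """MR-Egger: weighted regression of Gamma on gamma with an intercept.

    Instruments are first oriented so that every gamma is positive (jointly
    flipping the signs of gamma and Gamma), the convention under which the
    intercept estimates directional pleiotropy.  Weights are 1/sigma_y^2;
    standard errors use multiplicative overdispersion floored at 1, and
    p-values are two-sided normal.
    """
    J = len(instruments)
    if J < 3:
        raise ValueError("MR-Egger requires at least three instruments")
    g, _, G, sy = _arrays(instruments)
    flip = np.sign(g)
    if np.any(flip == 0):
        raise ZeroDivisionError("MR-Egger requires gamma != 0")
    g = g * flip
    G = G * flip
    if np.allclose(g, g[0]):
        raise np.linalg.LinAlgError("degenerate design: all oriented gamma identical")

    X = sm.add_constant(g)
    fit = sm.WLS(G, X, weights=1.0 / (sy * sy)).fit()
    # statsmodels scales the covariance by RSS/(J-2); refloor the dispersion
    # at 1 so that homogeneous data keep the analytic first-order SE.
    disp = max(1.0, float(fit.scale))
    se_unscaled = np.sqrt(np.diag(fit.normalized_cov_params))
    icept, slope = float(fit.params[0]), float(fit.params[1])
    se_icept, se_slope = (float(s * math.sqrt(disp)) for s in se_unscaled)

    slope_est = _normal_estimate("egger_slope", slope, se_slope, J)
    return EggerResult(
        slope=slope_est,
        intercept=icept,
        intercept_se=se_icept,
        intercept_pval=float(2.0 * norm.sf(abs(icept) / se_icept)),
    )


def to_or_per_sd_decrease(est: MrEstimate) -> OrResult:
    """Odds ratio (with 95% CI) per one SD *decrease* of the exposure.

    For an estimate on the log-odds scale per SD increase, OR = exp(-beta);
    the CI bounds are exp(-beta -/+ 1.96 se), returned in ascending order.
    """
    lo = math.exp(-est.beta_hat - Z95 * est.se)
    hi = math.exp(-est.beta_hat + Z95 * est.se)
    lo, hi = min(lo, hi), max(lo, hi)
    return OrResult(math.exp(-est.beta_hat), lo, hi)


def estimates_to_frame(rows: Sequence[tuple[str, MrEstimate]]):
    """Forest-plot-ready table of (outcome, method) estimate rows."""
    import pandas as pd

    out = []
    for outcome, est in rows:
        orr = to_or_per_sd_decrease(est)
        out.append(
            {
                "outcome": outcome,
                "method": est.method,
                "n_snps": est.n_snps,
                "beta": est.beta_hat,
                "se": est.se,
                "ci_low": est.ci_low,
                "ci_high": est.ci_high,
                "pval": est.pval,
                "q": est.q_stat,
                "q_pval": est.q_pval,
                "i2": est.i2,
                "or_per_sd_decrease": orr.or_per_sd_decrease,
                "or_ci_low": orr.ci_low,
                "or_ci_high": orr.ci_high,
            }
        )
    return pd.DataFrame(out)
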