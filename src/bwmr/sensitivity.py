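"""Outlier and robustness diagnostics for two-sample MR.

Leave-one-out re-estimation exposes single influential instruments; the
MR-PRESSO residual-sum-of-squares test detects horizontal pleiotropy globally
and per instrument by parametric simulation from the fitted no-pleiotropy
model; funnel data (ratio vs precision) supports the visual symmetry check;
and the reverse analysis re-runs the pipeline with exposure and outcome roles
swapped to probe reverse causation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .estimators import MrEstimate, ivw, wald_ratio
from .summary_io import HarmonizedInstrument, SummaryStatsTable, harmonize_tables

__all__ = [
    "LooTable",
    "PressoResult",
    "leave_one_out",
    "mr_presso",
    "funnel_data",
    "reverse_analysis",
]


@dataclass(frozen=True)
class LooTable:
    rows: tuple[tuple[str, MrEstimate], ...]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "left_out_snp_id": snp,
                    "beta": est.beta_hat,
                    "se": est.se,
                    "ci_low": est.ci_low,
                    "ci_high": est.ci_high,
                    "pval": est.pval,
                    "n_snps": est.n_snps,
                }
                for snp, est in self.rows
            ]
        )


@dataclass(frozen=True)
class PressoResult:
    global_rss: float
    global_pval: float
    per_snp_pvals: tuple[float, ...]
    outliers: tuple[str, ...]
    n_sim: int
    seed: int
    distortion: float | None = None  # descriptive only: beta(all) - beta(non-outliers)


def leave_one_out(
    instruments: Sequence[HarmonizedInstrument],
    estimator: Callable[[Sequence[HarmonizedInstrument]], MrEstimate] | None = None,
) -> LooTable:
    """Re-fit the estimator J times, each time excluding one instrument.

    ``estimator`` defaults to random-effects IVW.  With J = 2 each row
    reduces to the remaining instrument's Wald ratio (IVW at J = 1).
    """
    J = len(instruments)
    if J < 2:
        raise ValueError("leave-one-out requires at least two instruments")
    if estimator is None:
        estimator = lambda ins: ivw(ins, mode="random")
    rows = []
    for j in range(J):
        rest = [h for k, h in enumerate(instruments) if k != j]
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # J-1 = 1 random->fixed fallback
            rows.append((instruments[j].snp_id, estimator(rest)))
    return LooTable(tuple(rows))


def mr_presso(
    instruments: Sequence[HarmonizedInstrument],
    n_sim: int = 1000,
    seed: int | np.random.Generator = 0,
    alpha: float = 0.05,
) -> PressoResult:
    """MR-PRESSO global and per-instrument outlier test.

    The observed statistic is the variance-standardized residual sum of
    squares, where instrument j's residual is Gamma_j - theta_(-j) * gamma_j
    against the leave-j-out IVW fit.  Its null distribution is generated by
    ``n_sim`` parametric draws gamma* ~ N(gamma, sigma_x^2),
    Gamma* ~ N(theta_(-j) gamma_j, sigma_y^2) from the fitted no-pleiotropy
    model.  Per-SNP p-values compare each observed squared residual to its
    simulated contribution distribution and are Bonferroni-corrected at
    ``alpha`` to flag outliers.  Bit-for-bit reproducible given (n_sim, seed).
    """
    J = len(instruments)
    if J < 4:
        raise ValueError("MR-PRESSO requires at least four instruments")
    seed_val = seed if isinstance(seed, (int, np.integer)) else -1
    rng = np.random.default_rng(seed)
    g = np.array([h.gamma for h in instruments])
    sx = np.array([h.sigma_x for h in instruments])
    G = np.array([h.Gamma_out for h in instruments])
    sy = np.array([h.sigma_y for h in instruments])

    def loo_betas(gv: np.ndarray, Gv: np.ndarray) -> np.ndarray:
        # IVW slope excluding each j in turn, vectorized over j
        w = gv * gv / (sy * sy)
        num, den = np.sum(w * Gv / gv), np.sum(w)
        return (num - w * Gv / gv) / (den - w)

    def rss_and_contrib(gv: np.ndarray, Gv: np.ndarray) -> tuple[float, np.ndarray]:
        beta_loo = loo_betas(gv, Gv)
        resid = Gv - beta_loo * gv
        var = sy * sy + (beta_loo * sx) ** 2  # delta-method residual variance
        contrib = resid * resid / var
        return float(np.sum(contrib)), contrib

    rss_obs, contrib_obs = rss_and_contrib(g, G)
    beta_loo_obs = loo_betas(g, G)

    g_sim = rng.normal(g, sx, size=(n_sim, J))
    G_sim = rng.normal(beta_loo_obs * g, sy, size=(n_sim, J))
    rss_sim = np.empty(n_sim)
    contrib_sim = np.empty((n_sim, J))
    for s in range(n_sim):
        rss_sim[s], contrib_sim[s] = rss_and_contrib(g_sim[s], G_sim[s])

    global_pval = float((np.sum(rss_sim >= rss_obs) + 1) / (n_sim + 1))
    per_snp = (np.sum(contrib_sim >= contrib_obs, axis=0) + 1) / (n_sim + 1)
    flagged = tuple(
        instruments[j].snp_id for j in range(J) if per_snp[j] < alpha / J
    )

    distortion = None
    if flagged and len(flagged) < J - 1:
        keep = [h for h in instruments if h.snp_id not in set(flagged)]
        distortion = ivw(list(instruments), mode="fixed").beta_hat - ivw(keep, mode="fixed").beta_hat
    return PressoResult(
        global_rss=rss_obs,
        global_pval=global_pval,
        per_snp_pvals=tuple(float(p) for p in per_snp),
        outliers=flagged,
        n_sim=n_sim,
        seed=int(seed_val),
        distortion=distortion,
    )


def funnel_data(instruments: Sequence[HarmonizedInstrument]) -> pd.DataFrame:
    """Per-instrument (ratio, precision) pairs for funnel plots.

    ratio = Gamma/gamma, precision = |gamma|/sigma_y (the inverse of the
    first-order Wald-ratio SE).  Instruments with gamma = 0 are dropped with
    a warning.
    """
    if len(instruments) < 1:
        raise ValueError("funnel_data requires at least one instrument")
    rows = []
    for h in instruments:
        if h.gamma == 0:
            import warnings

            warnings.warn(f"{h.snp_id}: gamma = 0, dropped from funnel data", stacklevel=2)
            continue
        beta, se = wald_ratio(h)
        rows.append({"snp_id": h.snp_id, "ratio": beta, "precision": 1.0 / se})
    return pd.DataFrame(rows, columns=["snp_id", "ratio", "precision"])


def reverse_analysis(
    outcome_instruments: SummaryStatsTable,
    exposure_as_outcome: SummaryStatsTable,
    estimator: Callable[[Sequence[HarmonizedInstrument]], MrEstimate] | None = None,
    palindromic_eaf_window: float = 0.08,
) -> MrEstimate:
    """MR with the roles swapped: disease instruments against the exposure.

    Computationally identical to the forward pipeline; the result's method
    tag carries a ``reverse:`` prefix.
    """
    if estimator is None:
        estimator = lambda ins: ivw(ins, mode="random")
    harmonized, _ = harmonize_tables(
        outcome_instruments, exposure_as_outcome, palindromic_eaf_window
    )
    if not harmonized:
        raise ValueError("no instruments could be harmonized for the reverse analysis")
    est = estimator(harmonized)
    from dataclasses import replace

    return replace(est, method=f"reverse:{est.method}")
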