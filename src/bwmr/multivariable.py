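"""Multivariable MR and the total/direct/indirect effect decomposition.

Regressing the outcome effects jointly on the effects for several exposures
(weights 1/sigma_y^2, no intercept) isolates each exposure's direct effect;
with birth weight and one candidate mediator, the birth-weight coefficient is
the direct effect and the difference total - direct (log-odds scale) is the
indirect, mediated effect.  Odds-ratio reporting follows the per-SD-decrease
convention of the univariable estimators.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import norm

from .estimators import MrEstimate, OrResult, Z95, _normal_estimate, to_or_per_sd_decrease

__all__ = ["MvInstrumentRow", "MvResult", "Decomposition", "mv_ivw", "decompose"]


@dataclass(frozen=True)
class MvInstrumentRow:
    """One instrument's effects on every exposure plus the outcome."""

    snp_id: str
    gamma_by_exposure: tuple[float, ...]
    sigma_x_by_exposure: tuple[float, ...]
    Gamma_out: float
    sigma_y: float

    def __post_init__(self) -> None:
        if len(self.gamma_by_exposure) != len(self.sigma_x_by_exposure):
            raise ValueError("gamma and sigma_x lengths differ")
        if any(s <= 0 for s in self.sigma_x_by_exposure) or self.sigma_y <= 0:
            raise ValueError("standard errors must be positive")


@dataclass(frozen=True)
class MvResult:
    exposures: tuple[str, ...]
    estimates: tuple[MrEstimate, ...]

    def by_exposure(self, name: str) -> MrEstimate:
        return self.estimates[self.exposures.index(name)]


@dataclass(frozen=True)
class Decomposition:
    total: MrEstimate
    direct: MrEstimate
    indirect_beta: float
    indirect_se: float
    indirect_ci: tuple[float, float]
    indirect_pval: float

    @property
    def or_scale(self) -> dict[str, OrResult]:
        ind = OrResult(
            math.exp(-self.indirect_beta),
            math.exp(-self.indirect_beta - Z95 * self.indirect_se),
            math.exp(-self.indirect_beta + Z95 * self.indirect_se),
        )
        lo, hi = sorted((ind.ci_low, ind.ci_high))
        return {
            "total": to_or_per_sd_decrease(self.total),
            "direct": to_or_per_sd_decrease(self.direct),
            "indirect": OrResult(ind.or_per_sd_decrease, lo, hi),
        }

    def to_frame(self) -> pd.DataFrame:
        ors = self.or_scale
        rows = []
        for name, est in (("total", self.total), ("direct", self.direct)):
            rows.append(
                {
                    "effect": name,
                    "beta": est.beta_hat,
                    "se": est.se,
                    "pval": est.pval,
                    "or_per_sd_decrease": ors[name].or_per_sd_decrease,
                    "or_ci_low": ors[name].ci_low,
                    "or_ci_high": ors[name].ci_high,
                }
            )
        rows.append(
            {
                "effect": "indirect",
                "beta": self.indirect_beta,
                "se": self.indirect_se,
                "pval": self.indirect_pval,
                "or_per_sd_decrease": ors["indirect"].or_per_sd_decrease,
                "or_ci_low": ors["indirect"].ci_low,
                "or_ci_high": ors["indirect"].ci_high,
            }
        )
        return pd.DataFrame(rows)


def mv_ivw(
    rows: Sequence[MvInstrumentRow],
    exposure_names: Sequence[str] | None = None,
) -> MvResult:
    """Multivariable IVW: WLS of Gamma on all exposure-effect columns.

    No intercept; weights 1/sigma_y^2.  Requires more instruments than
    exposures and a full-rank design.  SEs use multiplicative overdispersion
    floored at 1, as in the univariable random-effects IVW.
    """
    if not rows:
        raise ValueError("mv_ivw requires at least one instrument row")
    K = len(rows[0].gamma_by_exposure)
    if any(len(r.gamma_by_exposure) != K for r in rows):
        raise ValueError("inconsistent exposure count across rows")
    J = len(rows)
    if J <= K:
        raise ValueError(f"need more instruments ({J}) than exposures ({K})")
    names = tuple(exposure_names) if exposure_names else tuple(f"exposure_{k}" for k in range(K))
    if len(names) != K:
        raise ValueError("exposure_names length mismatch")

    X = np.array([r.gamma_by_exposure for r in rows], dtype=float)
    y = np.array([r.Gamma_out for r in rows], dtype=float)
    sy = np.array([r.sigma_y for r in rows], dtype=float)
    if np.linalg.matrix_rank(X) < K:
        raise np.linalg.LinAlgError(
            f"rank-deficient design: exposure-effect columns {names} are collinear"
        )
    fit = sm.WLS(y, X, weights=1.0 / (sy * sy)).fit()
    disp = max(1.0, float(fit.scale)) if J > K else 1.0
    se_unscaled = np.sqrt(np.diag(fit.normalized_cov_params))
    ests = tuple(
        _normal_estimate(
            f"mv_ivw[{names[k]}]",
            float(fit.params[k]),
            float(se_unscaled[k] * math.sqrt(disp)),
            J,
        )
        for k in range(K)
    )
    return MvResult(exposures=names, estimates=ests)


def decompose(total: MrEstimate, direct: MrEstimate) -> Decomposition:
    """Total/direct/indirect decomposition on the log-odds scale.

    indirect = total - direct (the network-MR difference method); its SE is
    the conservative independence approximation sqrt(se_total^2 +
    se_direct^2).  OR-scale values use exp(-beta), i.e. per SD decrease.
    """
    beta = total.beta_hat - direct.beta_hat
    se = math.sqrt(total.se**2 + direct.se**2)
    return Decomposition(
        total=total,
        direct=direct,
        indirect_beta=beta,
        indirect_se=se,
        indirect_ci=(beta - Z95 * se, beta + Z95 * se),
        indirect_pval=float(2.0 * norm.sf(abs(beta) / se)),
    )
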