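"""Analytic statistical power for two-sample MR with a binary outcome.

Under the IVW estimator, the non-centrality of the two-sided Wald test at an
alternative odds ratio OR per exposure SD is approximately

    z* = |ln OR| * sqrt(n_outcome * PVE * cf * (1 - cf)),

where PVE is the exposure variance jointly explained by the instruments and
cf the outcome case fraction.  Power at level alpha is then
Phi(z* - z_{1-alpha/2}) + Phi(-z* - z_{1-alpha/2}).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import pandas as pd
from scipy.stats import norm

__all__ = ["PowerQuery", "mr_power_binary", "power_grid"]


@dataclass(frozen=True)
class PowerQuery:
    n_outcome: int
    pve: float
    case_fraction: float
    or_alt: float
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.n_outcome < 1:
            raise ValueError("n_outcome must be positive")
        if not 0.0 < self.pve < 1.0:
            raise ValueError("pve must lie in (0, 1)")
        if not 0.0 < self.case_fraction < 1.0:
            raise ValueError("case_fraction must lie in (0, 1)")
        if self.or_alt <= 0:
            raise ValueError("or_alt must be positive")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")


def mr_power_binary(q: PowerQuery) -> float:
    """Power of the two-sided IVW test under the alternative ``q.or_alt``."""
    z_crit = norm.ppf(1.0 - q.alpha / 2.0)
    ncp = abs(math.log(q.or_alt)) * math.sqrt(
        q.n_outcome * q.pve * q.case_fraction * (1.0 - q.case_fraction)
    )
    return float(norm.cdf(ncp - z_crit) + norm.cdf(-ncp - z_crit))


def power_grid(
    n_outcomes: Sequence[int],
    or_alts: Sequence[float],
    pve: float,
    case_fraction: float,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Power over a grid of outcome sample sizes and alternative ORs."""
    rows = [
        {
            "n_outcome": n,
            "or_alt": o,
            "pve": pve,
            "case_fraction": case_fraction,
            "alpha": alpha,
            "power": mr_power_binary(PowerQuery(n, pve, case_fraction, o, alpha)),
        }
        for n in n_outcomes
        for o in or_alts
    ]
    return pd.DataFrame(rows)
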