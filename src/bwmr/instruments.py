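"""Instrument-strength diagnostics and instrument selection filters.

A SNP is a usable instrument for Mendelian randomization when it is robustly
associated with the exposure.  Strength is summarized by the proportion of
phenotypic variance explained (PVE), computable from summary statistics as

    PVE = beta^2 / (beta^2 + n * se^2),

and by the F statistic, F = (beta / se)^2, with F > 10 the conventional bar
against weak-instrument bias.  Selection applies a genome-wide p-value
threshold with optional greedy LD clumping; pleiotropy screening removes
instruments that associate too strongly with the outcome itself or appear on
a caller-supplied exclusion list (e.g. from a pleiotropy database query done
outside this package).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np

from .summary_io import SnpAssociation, SummaryStatsTable

__all__ = [
    "InstrumentDiagnostics",
    "EmptyInstrumentError",
    "compute_pve",
    "compute_f",
    "overall_f",
    "diagnostics",
    "select_instruments",
    "exclude_pleiotropic",
]

#: Bonferroni outcome-association threshold used by the source study for its
#: 47 instruments: 0.05 / 47.
DEFAULT_PLEIOTROPY_P = 0.05 / 47


class EmptyInstrumentError(ValueError):
    """Raised when a selection or exclusion step leaves no instruments."""


@dataclass(frozen=True)
class InstrumentDiagnostics:
    snp_ids: tuple[str, ...]
    per_snp_pve: tuple[float, ...]
    per_snp_f: tuple[float, ...]
    overall_f: float


def compute_pve(beta: float, se: float, n: int) -> float:
    """Proportion of exposure variance explained by one SNP.

    Uses the summary-statistics identity PVE = beta^2 / (beta^2 + n se^2),
    which follows from the regression R^2 with var(x) recovered from the
    sampling variance of the effect estimate.
    """
    if se <= 0:
        raise ValueError(f"se must be positive, got {se}")
    if n < 2:
        raise ValueError(f"n must be >= 2, got {n}")
    b2 = beta * beta
    return b2 / (b2 + n * se * se)


def compute_f(beta: float, se: float) -> float:
    """Per-SNP instrument-strength F statistic, (beta/se)^2."""
    if se <= 0:
        raise ValueError(f"se must be positive, got {se}")
    z = beta / se
    return z * z


def overall_f(table: SummaryStatsTable) -> float:
    """Arithmetic mean of the per-SNP F statistics across a table."""
    if len(table) == 0:
        raise EmptyInstrumentError("cannot compute overall F of an empty table")
    return float(np.mean([compute_f(r.beta, r.se) for r in table]))


def diagnostics(table: SummaryStatsTable) -> InstrumentDiagnostics:
    if len(table) == 0:
        raise EmptyInstrumentError("cannot compute diagnostics of an empty table")
    ids = tuple(r.snp_id for r in table)
    pve = tuple(compute_pve(r.beta, r.se, r.n) for r in table)
    f = tuple(compute_f(r.beta, r.se) for r in table)
    return InstrumentDiagnostics(ids, pve, f, float(np.mean(f)))


def select_instruments(
    table: SummaryStatsTable,
    p_threshold: float = 5e-8,
    ld: Mapping[tuple[str, str], float] | Callable[[str, str], float] | None = None,
    r2_cutoff: float = 0.01,
) -> SummaryStatsTable:
    """Keep genome-wide-significant SNPs, optionally greedily LD-clumped.

    ``ld`` supplies pairwise r-squared values, either as a mapping keyed by
    (snp_id, snp_id) pairs (orientation-insensitive; missing pairs are
    treated as independent) or as a callable.  ``ld=None`` assumes all SNPs
    independent.  Clumping repeatedly keeps the smallest-p SNP and removes
    every remaining SNP with r^2 > ``r2_cutoff`` against it.
    """
    if not 0.0 < p_threshold < 1.0:
        raise ValueError("p_threshold must lie in (0, 1)")
    candidates = [r for r in table if r.pval < p_threshold]
    if not candidates:
        raise EmptyInstrumentError(
            f"no SNP passes p < {p_threshold:g} in table '{table.trait_label}'"
        )
    if ld is None:
        kept = candidates
    else:
        if callable(ld):
            r2 = ld
        else:
            pairs = dict(ld)

            def r2(a: str, b: str) -> float:
                return pairs.get((a, b), pairs.get((b, a), 0.0))

        remaining = sorted(candidates, key=lambda r: r.pval)
        kept_ids: list[str] = []
        while remaining:
            lead = remaining.pop(0)
            kept_ids.append(lead.snp_id)
            remaining = [r for r in remaining if r2(lead.snp_id, r.snp_id) <= r2_cutoff]
        order = {r.snp_id: i for i, r in enumerate(table)}
        kept = sorted(
            [r for r in candidates if r.snp_id in set(kept_ids)],
            key=lambda r: order[r.snp_id],
        )
    return SummaryStatsTable(kept, trait_label=table.trait_label, trait_type=table.trait_type)


def exclude_pleiotropic(
    instruments: SummaryStatsTable,
    outcome: SummaryStatsTable,
    p_threshold: float = DEFAULT_PLEIOTROPY_P,
    explicit_exclusions: Iterable[str] = (),
) -> tuple[SummaryStatsTable, list[tuple[str, str]]]:
    """Drop instruments with outcome-side p below ``p_threshold`` and any id
    in ``explicit_exclusions``; returns (kept table, [(snp_id, reason), ...]).
    """
    if not 0.0 < p_threshold < 1.0:
        raise ValueError("p_threshold must lie in (0, 1)")
    explicit = set(explicit_exclusions)
    kept: list[SnpAssociation] = []
    dropped: list[tuple[str, str]] = []
    for rec in instruments:
        if rec.snp_id in explicit:
            dropped.append((rec.snp_id, "explicit exclusion"))
            continue
        out = outcome.get(rec.snp_id)
        if out is not None and out.pval < p_threshold:
            dropped.append((rec.snp_id, f"outcome p={out.pval:.3g} < {p_threshold:.3g}"))
            continue
        kept.append(rec)
    if not kept:
        raise EmptyInstrumentError("all instruments excluded as potentially pleiotropic")
    return (
        SummaryStatsTable(kept, trait_label=instruments.trait_label, trait_type=instruments.trait_type),
        dropped,
    )
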