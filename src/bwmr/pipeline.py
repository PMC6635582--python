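"""End-to-end orchestration of the MR analysis across multiple outcomes.

One run takes a single exposure table and any number of outcome tables,
harmonizes each outcome against the exposure, optionally applies the
pleiotropy exclusion filter, computes instrument diagnostics, fits the
estimator ensemble (fixed/random IVW, weighted median, MR-Egger) plus the
enabled sensitivity analyses, and applies a Bonferroni threshold of
0.05 / (number of outcomes) to the primary random-effects IVW p-values.
Failures in one outcome are recorded and do not abort the others.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import __version__
from .estimators import (
    MrEstimate,
    egger,
    estimates_to_frame,
    ivw,
    to_or_per_sd_decrease,
    weighted_median,
)
from .instruments import diagnostics, exclude_pleiotropic, select_instruments
from .sensitivity import funnel_data, leave_one_out, mr_presso
from .summary_io import (
    SummaryStatsTable,
    TraitType,
    harmonize_tables,
    read_summary_stats,
)

logger = logging.getLogger("bwmr")

__all__ = ["OutcomeSpec", "AnalysisConfig", "OutcomeResult", "AnalysisReport", "run_analysis"]


@dataclass(frozen=True)
class OutcomeSpec:
    label: str
    table: SummaryStatsTable | str | Path
    trait_type: TraitType = TraitType.binary


@dataclass(frozen=True)
class AnalysisConfig:
    """Configuration of one multi-outcome analysis run.

    ``exposure`` and each outcome may be given as an in-memory table or a
    TSV path in the standard schema.  ``instrument_p_threshold=None`` skips
    instrument re-selection (the exposure table is taken as the instrument
    list); ``pleiotropy_p=None`` skips the outcome-association exclusion
    filter.  ``seed`` drives every stochastic stage (weighted-median
    bootstrap, MR-PRESSO).
    """

    exposure: SummaryStatsTable | str | Path
    outcomes: tuple[OutcomeSpec, ...]
    instrument_p_threshold: float | None = None
    pleiotropy_p: float | None = None
    explicit_exclusions: tuple[str, ...] = ()
    palindromic_eaf_window: float = 0.08
    run_weighted_median: bool = True
    run_egger: bool = True
    run_loo: bool = False
    run_presso: bool = False
    presso_n_sim: int = 1000
    median_n_boot: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.outcomes:
            raise ValueError("at least one outcome is required")


@dataclass
class OutcomeResult:
    label: str
    estimates: dict[str, MrEstimate]
    n_harmonized: int
    dropped: list[tuple[str, str]]
    diagnostics: dict
    loo: pd.DataFrame | None = None
    presso: dict | None = None
    funnel: pd.DataFrame | None = None
    error: str | None = None


@dataclass
class AnalysisReport:
    results: list[OutcomeResult]
    bonferroni_threshold: float
    provenance: dict

    def significant(self) -> list[str]:
        """Outcomes whose primary (random-effects IVW) p-value clears the
        Bonferroni threshold."""
        out = []
        for res in self.results:
            primary = res.estimates.get("ivw_random")
            if primary is not None and primary.pval < self.bonferroni_threshold:
                out.append(res.label)
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (res.label, est)
            for res in self.results
            if res.error is None
            for est in res.estimates.values()
        ]
        frame = estimates_to_frame(rows)
        if len(frame):
            frame["bonferroni_significant"] = [
                (m == "ivw_random") and (p < self.bonferroni_threshold)
                for m, p in zip(frame["method"], frame["pval"])
            ]
        return frame

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.to_frame().to_csv(out / "estimates.tsv", sep="\t", index=False)
        for res in self.results:
            if res.dropped:
                pd.DataFrame(res.dropped, columns=["snp_id", "reason"]).to_csv(
                    out / f"excluded_{res.label}.tsv", sep="\t", index=False
                )
            if res.loo is not None:
                res.loo.to_csv(out / f"loo_{res.label}.tsv", sep="\t", index=False)
            if res.funnel is not None:
                res.funnel.to_csv(out / f"funnel_{res.label}.tsv", sep="\t", index=False)
            if res.presso is not None:
                with open(out / f"presso_{res.label}.txt", "w") as fh:
                    for k, v in res.presso.items():
                        fh.write(f"{k}\t{v}\n")
        with open(out / "summary.txt", "w") as fh:
            fh.write(self.summary_text())

    def summary_text(self) -> str:
        lines = [
            f"bwmr {self.provenance['version']} analysis summary",
            f"outcomes: {len(self.results)}; Bonferroni threshold "
            f"0.05/{len(self.results)} = {self.bonferroni_threshold:.3g}",
            f"seed: {self.provenance['seed']}",
            "",
        ]
        for res in self.results:
            if res.error is not None:
                lines.append(f"[{res.label}] FAILED: {res.error}")
                continue
            primary = res.estimates.get("ivw_random")
            orr = to_or_per_sd_decrease(primary)
            flag = "*" if primary.pval < self.bonferroni_threshold else " "
            lines.append(
                f"[{res.label}]{flag} J={res.n_harmonized} "
                f"OR/SD-decrease={orr.or_per_sd_decrease:.3f} "
                f"(95% CI {orr.ci_low:.3f}-{orr.ci_high:.3f}) p={primary.pval:.3g} "
                f"Q={primary.q_stat:.2f} I2={100 * primary.i2:.1f}%"
            )
        return "\n".join(lines) + "\n"


def _load(table, trait_type=TraitType.continuous, label=None) -> SummaryStatsTable:
    if isinstance(table, SummaryStatsTable):
        return table
    return read_summary_stats(table, trait_type=trait_type, trait_label=label)


def run_analysis(cfg: AnalysisConfig) -> AnalysisReport:
    """Run the full pipeline for every configured outcome."""
    exposure = _load(cfg.exposure, TraitType.continuous, "exposure")
    if cfg.instrument_p_threshold is not None:
        exposure = select_instruments(exposure, cfg.instrument_p_threshold)
        logger.info("instrument selection kept %d SNPs", len(exposure))

    m = len(cfg.outcomes)
    threshold = 0.05 / m
    results: list[OutcomeResult] = []
    for i, spec in enumerate(cfg.outcomes):
        try:
            results.append(
                _run_one(cfg, exposure, spec, seed=cfg.seed + 1000 * i)
            )
        except Exception as exc:  # keep going for the other outcomes
            logger.error("[%s] failed: %s", spec.label, exc)
            results.append(
                OutcomeResult(
                    label=spec.label,
                    estimates={},
                    n_harmonized=0,
                    dropped=[],
                    diagnostics={},
                    error=f"{type(exc).__name__}: {exc}",
                )
            )
    provenance = {
        "version": __version__,
        "seed": cfg.seed,
        "n_outcomes": m,
        "instrument_p_threshold": cfg.instrument_p_threshold,
        "pleiotropy_p": cfg.pleiotropy_p,
        "palindromic_eaf_window": cfg.palindromic_eaf_window,
        "presso_n_sim": cfg.presso_n_sim,
        "median_n_boot": cfg.median_n_boot,
    }
    return AnalysisReport(results=results, bonferroni_threshold=threshold, provenance=provenance)


def _run_one(cfg: AnalysisConfig, exposure: SummaryStatsTable, spec: OutcomeSpec, seed: int) -> OutcomeResult:
    outcome = _load(spec.table, spec.trait_type, spec.label)
    instruments_table = exposure
    dropped: list[tuple[str, str]] = []
    if cfg.pleiotropy_p is not None or cfg.explicit_exclusions:
        instruments_table, excl = exclude_pleiotropic(
            exposure,
            outcome,
            p_threshold=cfg.pleiotropy_p if cfg.pleiotropy_p is not None else 1.0 - 1e-12,
            explicit_exclusions=cfg.explicit_exclusions,
        )
        dropped.extend(excl)
        logger.info("[%s] pleiotropy filter dropped %d instruments", spec.label, len(excl))

    harmonized, harm_drops = harmonize_tables(
        instruments_table, outcome, cfg.palindromic_eaf_window
    )
    dropped.extend((d.snp_id, d.reason) for d in harm_drops)
    logger.info(
        "[%s] %d instruments harmonized, %d dropped", spec.label, len(harmonized), len(harm_drops)
    )
    if not harmonized:
        raise ValueError("no instruments survive harmonization")

    diag = diagnostics(instruments_table.subset([h.snp_id for h in harmonized]))
    estimates: dict[str, MrEstimate] = {}
    estimates["ivw_fixed"] = ivw(harmonized, mode="fixed")
    estimates["ivw_random"] = ivw(harmonized, mode="random")
    if cfg.run_weighted_median and len(harmonized) >= 3:
        estimates["weighted_median"] = weighted_median(
            harmonized, n_boot=cfg.median_n_boot, seed=seed
        )
    egger_extra = {}
    if cfg.run_egger and len(harmonized) >= 3:
        eg = egger(harmonized)
        estimates["egger_slope"] = eg.slope
        egger_extra = {
            "egger_intercept": eg.intercept,
            "egger_intercept_se": eg.intercept_se,
            "egger_intercept_pval": eg.intercept_pval,
        }

    loo_frame = leave_one_out(harmonized).to_frame() if cfg.run_loo and len(harmonized) >= 2 else None
    presso_dict = None
    if cfg.run_presso and len(harmonized) >= 4:
        pr = mr_presso(harmonized, n_sim=cfg.presso_n_sim, seed=seed + 1)
        presso_dict = {
            "global_rss": pr.global_rss,
            "global_pval": pr.global_pval,
            "outliers": ",".join(pr.outliers) or "none",
            "n_sim": pr.n_sim,
            "seed": pr.seed,
        }

    return OutcomeResult(
        label=spec.label,
        estimates=estimates,
        n_harmonized=len(harmonized),
        dropped=dropped,
        diagnostics={
            "overall_f": diag.overall_f,
            "total_pve": float(sum(diag.per_snp_pve)),
            **egger_extra,
        },
        loo=loo_frame,
        presso=presso_dict,
        funnel=funnel_data(harmonized),
    )
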