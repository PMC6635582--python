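"""Reading, validation, writing and harmonization of GWAS summary statistics.

Two-sample Mendelian randomization works entirely from marginal per-SNP
association tables: for the exposure (birth weight, SD units) each record
carries the per-allele effect ``gamma`` with standard error ``sigma_x``; for
a binary outcome the effect is on the log-odds scale (``Gamma``, ``sigma_y``).
Before any estimation the two tables must be harmonized so that both effects
refer to the same effect allele; this module implements the standard
match / swap / strand-flip logic with an explicit drop rule for ambiguous
palindromic variants.
"""

from __future__ import annotations

import importlib.resources
import math
import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = [
    "TraitType",
    "SnpAssociation",
    "SummaryStatsTable",
    "HarmonizedInstrument",
    "DropDecision",
    "SummaryStatsFormatError",
    "HarmonizationError",
    "read_summary_stats",
    "write_summary_stats",
    "harmonize",
    "harmonize_tables",
    "load_table1_fixture",
]

STANDARD_FIELDS = (
    "snp_id",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pval",
    "n",
)

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


class TraitType(str, Enum):
    continuous = "continuous"
    binary = "binary"


class SummaryStatsFormatError(ValueError):
    """Raised when a summary-statistics file violates the expected format."""


class HarmonizationError(ValueError):
    """Raised when exposure and outcome allele sets cannot be reconciled."""


@dataclass(frozen=True)
class SnpAssociation:
    """One SNP's marginal association with one trait.

    ``beta`` is the per-effect-allele effect: SD units for a continuous
    exposure, log-odds for a binary outcome.  ``eaf`` is the effect-allele
    frequency, ``n`` the per-SNP sample size.
    """

    snp_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    eaf: float
    beta: float
    se: float
    pval: float
    n: int

    def __post_init__(self) -> None:
        if self.se <= 0:
            raise ValueError(f"{self.snp_id}: se must be > 0, got {self.se}")
        if not 0.0 <= self.eaf <= 1.0:
            raise ValueError(f"{self.snp_id}: eaf must lie in [0, 1], got {self.eaf}")
        if self.pos < 1:
            raise ValueError(f"{self.snp_id}: pos must be >= 1 (1-based), got {self.pos}")
        if not 0.0 < self.pval <= 1.0:
            raise ValueError(f"{self.snp_id}: pval must lie in (0, 1], got {self.pval}")
        if self.n < 1:
            raise ValueError(f"{self.snp_id}: n must be positive, got {self.n}")
        if self.effect_allele == self.other_allele:
            raise ValueError(f"{self.snp_id}: effect and other allele are identical")
        # Printed tables are rounded, so the z-implied p-value is only checked
        # to an order of magnitude; disagreement warns rather than fails.
        z = abs(self.beta) / self.se
        p_implied = max(2.0 * norm.sf(z), 1e-300)
        if not (0.1 <= p_implied / max(self.pval, 1e-300) <= 10.0) and z > 0:
            warnings.warn(
                f"{self.snp_id}: reported p={self.pval:.3g} differs from "
                f"z-implied p={p_implied:.3g} by more than an order of magnitude",
                stacklevel=2,
            )

    def is_palindromic(self) -> bool:
        return _COMPLEMENT.get(self.effect_allele) == self.other_allele


@dataclass
class SummaryStatsTable:
    """An ordered collection of :class:`SnpAssociation` for one trait."""

    records: list[SnpAssociation]
    trait_label: str
    trait_type: TraitType = TraitType.continuous

    def __post_init__(self) -> None:
        self.trait_type = TraitType(self.trait_type)
        ids = [r.snp_id for r in self.records]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise SummaryStatsFormatError(
                f"duplicate snp_id in table '{self.trait_label}': {dupes}"
            )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def get(self, snp_id: str) -> SnpAssociation | None:
        for r in self.records:
            if r.snp_id == snp_id:
                return r
        return None

    def subset(self, snp_ids: Iterable[str]) -> "SummaryStatsTable":
        keep = set(snp_ids)
        return SummaryStatsTable(
            [r for r in self.records if r.snp_id in keep],
            trait_label=self.trait_label,
            trait_type=self.trait_type,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(r) for r in self.records], columns=STANDARD_FIELDS)


@dataclass(frozen=True)
class HarmonizedInstrument:
    """Exposure/outcome effect pair aligned to the same effect allele."""

    snp_id: str
    gamma: float
    sigma_x: float
    Gamma_out: float
    sigma_y: float

    def __post_init__(self) -> None:
        if self.sigma_x <= 0 or self.sigma_y <= 0:
            raise ValueError(f"{self.snp_id}: standard errors must be positive")


@dataclass(frozen=True)
class DropDecision:
    snp_id: str
    reason: str


def read_summary_stats(
    path,
    column_map: Mapping[str, str] | None = None,
    trait_type: TraitType | str = TraitType.continuous,
    trait_label: str | None = None,
    sep: str = "\t",
) -> SummaryStatsTable:
    """Read a delimited summary-statistics table into a validated container.

    ``column_map`` maps standard field names (see :data:`STANDARD_FIELDS`) to
    the column names used in the file, accommodating the heterogeneous headers
    of different GWAS consortia.  Rows that fail validation are rejected with
    their (1-based, header-exclusive) row numbers reported.
    """
    column_map = dict(column_map or {})
    frame = pd.read_csv(path, sep=sep, dtype=str)
    rename = {column_map.get(f, f): f for f in STANDARD_FIELDS}
    missing = [column_map.get(f, f) for f in STANDARD_FIELDS if column_map.get(f, f) not in frame.columns]
    if missing:
        raise SummaryStatsFormatError(
            f"{path}: missing mandatory column(s) "
            + ", ".join(f"'{m}' (field '{k}')" for m, k in zip(missing, [f for f in STANDARD_FIELDS if column_map.get(f, f) in missing]))
        )
    frame = frame.rename(columns=rename)

    records: list[SnpAssociation] = []
    errors: list[str] = []
    for i, row in enumerate(frame.itertuples(index=False), start=1):
        try:
            records.append(
                SnpAssociation(
                    snp_id=str(row.snp_id),
                    chrom=str(row.chrom),
                    pos=int(float(row.pos)),
                    effect_allele=str(row.effect_allele).upper(),
                    other_allele=str(row.other_allele).upper(),
                    eaf=float(row.eaf),
                    beta=float(row.beta),
                    se=float(row.se),
                    pval=float(row.pval),
                    n=int(float(row.n)),
                )
            )
        except (TypeError, ValueError) as exc:
            errors.append(f"row {i}: {exc}")
    if errors:
        raise SummaryStatsFormatError(f"{path}: {len(errors)} invalid row(s): " + "; ".join(errors))
    return SummaryStatsTable(
        records,
        trait_label=trait_label or str(path),
        trait_type=TraitType(trait_type),
    )


def write_summary_stats(table: SummaryStatsTable, path, sep: str = "\t") -> None:
    """Write a table in the standard TSV schema (round-trips with the reader)."""
    table.to_frame().to_csv(path, sep=sep, index=False)


def harmonize(
    exposure: SnpAssociation,
    outcome: SnpAssociation,
    palindromic_eaf_window: float = 0.08,
) -> HarmonizedInstrument | DropDecision:
    """Align an outcome record to the exposure's effect allele.

    Rules, applied in order:

    * identical alleles: pass through;
    * swapped alleles: sign-flip the outcome beta, complement its eaf;
    * palindromic pair (A/T or C/G) with either eaf within
      ``palindromic_eaf_window`` of 0.5: dropped as strand-ambiguous;
    * strand-flipped (complemented) alleles, matched or swapped: resolved as
      above;
    * anything else raises :class:`HarmonizationError`.
    """
    if exposure.snp_id != outcome.snp_id:
        raise HarmonizationError(
            f"snp_id mismatch: {exposure.snp_id} vs {outcome.snp_id}"
        )
    ea, oa = exposure.effect_allele, exposure.other_allele
    oea, ooa = outcome.effect_allele, outcome.other_allele

    if exposure.is_palindromic() or outcome.is_palindromic():
        w = palindromic_eaf_window
        if abs(exposure.eaf - 0.5) <= w or abs(outcome.eaf - 0.5) <= w:
            return DropDecision(exposure.snp_id, "ambiguous palindromic")

    def build(Gamma: float) -> HarmonizedInstrument:
        return HarmonizedInstrument(
            snp_id=exposure.snp_id,
            gamma=exposure.beta,
            sigma_x=exposure.se,
            Gamma_out=Gamma,
            sigma_y=outcome.se,
        )

    if (oea, ooa) == (ea, oa):
        return build(outcome.beta)
    if (oea, ooa) == (oa, ea):
        return build(-outcome.beta)

    cea, coa = _COMPLEMENT.get(oea), _COMPLEMENT.get(ooa)
    if (cea, coa) == (ea, oa):
        # opposite strand, same orientation: frequency check on the flip
        if _frequencies_compatible(exposure.eaf, outcome.eaf):
            return build(outcome.beta)
        return build(-outcome.beta)
    if (cea, coa) == (oa, ea):
        if _frequencies_compatible(exposure.eaf, 1.0 - outcome.eaf):
            return build(-outcome.beta)
        return build(outcome.beta)

    raise HarmonizationError(
        f"{exposure.snp_id}: allele sets incompatible "
        f"({ea}/{oa} vs {oea}/{ooa})"
    )


def _frequencies_compatible(f1: float, f2: float) -> bool:
    """True when the two effect-allele frequencies plausibly describe the
    same allele (closer to each other than to each other's complement)."""
    return abs(f1 - f2) <= abs(f1 - (1.0 - f2))


def harmonize_tables(
    exposure: SummaryStatsTable,
    outcome: SummaryStatsTable,
    palindromic_eaf_window: float = 0.08,
) -> tuple[list[HarmonizedInstrument], list[DropDecision]]:
    """Harmonize every exposure SNP available in the outcome table.

    Exposure SNPs missing from the outcome are dropped (reason
    ``"missing in outcome"``); the counts are visible in the returned drop
    list.  Proxy lookup and summary-statistic imputation are intentionally
    not performed.
    """
    kept: list[HarmonizedInstrument] = []
    dropped: list[DropDecision] = []
    for exp in exposure:
        out = outcome.get(exp.snp_id)
        if out is None:
            dropped.append(DropDecision(exp.snp_id, "missing in outcome"))
            continue
        result = harmonize(exp, out, palindromic_eaf_window)
        if isinstance(result, DropDecision):
            dropped.append(result)
        else:
            kept.append(result)
    return kept, dropped


def load_table1_fixture() -> SummaryStatsTable:
    """Load the packaged 47-SNP birth-weight instrument table.

    The fixture transcribes the published exposure-side instrument list:
    per-SNP effect (SD units of birth weight), SE, p, sample size and
    effect-allele frequency.  The frequency column is labelled MAF in the
    source but contains values above 0.5, i.e. it is the frequency of the
    listed effect allele and is loaded as ``eaf``.  The printed PVE and F
    columns are available via :func:`load_table1_frame` for cross-checks;
    diagnostics should be recomputed, not trusted.
    """
    frame = load_table1_frame()
    records = [
        SnpAssociation(
            snp_id=row.SNP,
            chrom=str(row.Chr),
            pos=int(row.Position),
            effect_allele=row.Allele.split("/")[0],
            other_allele=row.Allele.split("/")[1],
            eaf=float(row.MAF),
            beta=float(row.BETA),
            se=float(row.SE),
            pval=float(row.p),
            n=int(row.N),
        )
        for row in frame.itertuples(index=False)
    ]
    return SummaryStatsTable(records, trait_label="birth_weight", trait_type=TraitType.continuous)


def load_table1_frame() -> pd.DataFrame:
    """Raw fixture as printed (including the printed PVE and F columns)."""
    resource = importlib.resources.files("bwmr.data").joinpath(
        "table1_birthweight_instruments.tsv"
    )
    with importlib.resources.as_file(resource) as path:
        return pd.read_csv(path, sep="\t")


def write_drop_report(drops: Sequence[DropDecision], path, sep: str = "\t") -> None:
    pd.DataFrame([vars(d) for d in drops], columns=["snp_id", "reason"]).to_csv(
        path, sep=sep, index=False
    )
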