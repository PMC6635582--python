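"""Synthetic two-sample GWAS worlds with known causal structure.

Two generation paths are provided.  The summary-level path draws the
exposure- and outcome-side effect estimates directly from their sampling
distributions: per-SNP exposure effects are set from a target per-SNP PVE via
gamma_j^2 = pve_j / (2 maf_j (1 - maf_j)) (exposure variance 1), the outcome
truth is Gamma_j = theta * gamma_j + alpha_j with alpha_j an optional
horizontal-pleiotropy offset, and estimates are normal draws with the
standard two-sample standard errors (binary-outcome SEs on the log-odds
scale use the score-test approximation
sigma_y = 1/sqrt(n * cf * (1-cf) * 2 maf (1-maf))).  The individual-level
path simulates mother-child pairs — the child receives one maternal allele
and one population allele, forcing a genotype correlation of 0.5 — and is
used for maternal-effect analyses where the summary level cannot represent
the confounding structure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .summary_io import (
    SnpAssociation,
    SummaryStatsTable,
    TraitType,
    load_table1_fixture,
)

__all__ = [
    "SimulationConfig",
    "TwoSampleTruth",
    "MotherChildCohort",
    "simulate_two_sample",
    "simulate_mother_child",
    "table1_world",
    "paired_instruments",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Full description of a synthetic two-sample MR world.

    ``pve_per_snp`` and ``maternal_pve_per_snp`` accept a scalar (shared by
    all SNPs) or one value per SNP.  ``pleiotropy_frac`` is the fraction of
    instruments carrying a horizontal-pleiotropy offset
    alpha ~ N(pleiotropy_mean, pleiotropy_sd^2); directional pleiotropy has a
    nonzero mean, balanced pleiotropy mean zero.
    ``maternal_fetal_sign_concordance`` is the excess probability (over 1/2)
    scale: a maternal effect shares the fetal effect's sign with probability
    (1 + rho) / 2.  ``seed`` is mandatory.
    """

    n_snps: int
    theta: float
    n_exposure: int
    n_outcome: int
    case_fraction: float
    seed: int
    maf_range: tuple[float, float] = (0.1, 0.4)
    pve_per_snp: float | Sequence[float] = 3e-4
    pleiotropy_mean: float = 0.0
    pleiotropy_sd: float = 0.0
    pleiotropy_frac: float = 0.0
    maternal_pve_per_snp: float | Sequence[float] = 0.0
    maternal_direct_effect: float = 0.0
    maternal_fetal_sign_concordance: float = 0.1
    gamma_sign: str = "random"

    def __post_init__(self) -> None:
        if self.gamma_sign not in ("random", "positive"):
            raise ValueError("gamma_sign must be 'random' or 'positive'")
        if self.n_snps < 1:
            raise ValueError("n_snps must be positive")
        if self.n_exposure < 2 or self.n_outcome < 2:
            raise ValueError("sample sizes must be at least 2")
        if not 0.0 < self.case_fraction < 1.0:
            raise ValueError("case_fraction must lie in (0, 1)")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if not 0.0 <= self.pleiotropy_frac <= 1.0:
            raise ValueError("pleiotropy_frac must lie in [0, 1]")
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if np.sum(self.pve_vector()) >= 1.0:
            raise ValueError("total instrument PVE must be below 1")

    def _expand(self, value) -> np.ndarray:
        arr = np.asarray(value, dtype=float)
        if arr.ndim == 0:
            arr = np.full(self.n_snps, float(arr))
        if arr.shape != (self.n_snps,):
            raise ValueError(f"expected scalar or {self.n_snps} values, got shape {arr.shape}")
        if np.any(arr < 0) or np.any(arr >= 1):
            raise ValueError("per-SNP PVE values must lie in [0, 1)")
        return arr

    def pve_vector(self) -> np.ndarray:
        return self._expand(self.pve_per_snp)

    def maternal_pve_vector(self) -> np.ndarray:
        return self._expand(self.maternal_pve_per_snp)


@dataclass(frozen=True)
class TwoSampleTruth:
    """Latent quantities behind one synthetic world."""

    theta: float
    maf: np.ndarray
    gamma: np.ndarray
    alpha: np.ndarray
    sigma_x: np.ndarray
    sigma_y: np.ndarray
    seed: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "maf": self.maf,
                "gamma": self.gamma,
                "alpha": self.alpha,
                "sigma_x": self.sigma_x,
                "sigma_y": self.sigma_y,
            }
        )


@dataclass
class MotherChildCohort:
    """Individual-level mother-child pairs with birth weight and disease."""

    snp_ids: tuple[str, ...]
    maf: np.ndarray
    maternal_genotypes: np.ndarray  # (n, J) allele counts 0/1/2
    child_genotypes: np.ndarray
    birth_weight: np.ndarray  # SD units of the no-maternal-effect world
    disease: np.ndarray  # 0/1
    gamma: np.ndarray  # per-allele fetal effects
    vartheta: np.ndarray  # per-allele maternal effects
    theta: float
    case_fraction: float
    seed: int

    @property
    def n_individuals(self) -> int:
        return self.child_genotypes.shape[0]

    def genotype_correlations(self) -> np.ndarray:
        out = np.empty(len(self.snp_ids))
        for j in range(len(self.snp_ids)):
            out[j] = np.corrcoef(self.maternal_genotypes[:, j], self.child_genotypes[:, j])[0, 1]
        return out

    def to_tsv(self, genotype_path, phenotype_path) -> None:
        geno = pd.DataFrame(
            np.hstack([self.maternal_genotypes, self.child_genotypes]),
            columns=[f"mother_{s}" for s in self.snp_ids] + [f"child_{s}" for s in self.snp_ids],
        )
        geno.to_csv(genotype_path, sep="\t", index=False)
        pd.DataFrame(
            {"birth_weight": self.birth_weight, "disease": self.disease}
        ).to_csv(phenotype_path, sep="\t", index=False)


def _two_sided_p(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    return np.maximum(2.0 * norm.sf(np.abs(beta) / se), 1e-300)


def _make_table(ids, mafs, betas, ses, n, label, trait_type) -> SummaryStatsTable:
    pvals = _two_sided_p(betas, ses)
    records = [
        SnpAssociation(
            snp_id=ids[j],
            chrom="1",
            pos=j + 1,
            effect_allele="A",
            other_allele="G",
            eaf=float(mafs[j]),
            beta=float(betas[j]),
            se=float(ses[j]),
            pval=float(pvals[j]),
            n=int(n),
        )
        for j in range(len(ids))
    ]
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # null draws legitimately have |z| small
        return SummaryStatsTable(records, trait_label=label, trait_type=trait_type)


def simulate_two_sample(
    cfg: SimulationConfig,
) -> tuple[SummaryStatsTable, SummaryStatsTable, TwoSampleTruth]:
    """Draw one summary-level two-sample world from ``cfg``.

    Returns (exposure table, outcome table, truth record).  The two samples
    are non-overlapping by construction: estimate noise is drawn
    independently on each side.
    """
    rng = np.random.default_rng(cfg.seed)
    J = cfg.n_snps
    pve = cfg.pve_vector()
    maf = rng.uniform(cfg.maf_range[0], cfg.maf_range[1], size=J)
    het = 2.0 * maf * (1.0 - maf)
    signs = rng.choice([-1.0, 1.0], size=J) if cfg.gamma_sign == "random" else np.ones(J)
    gamma = signs * np.sqrt(pve / het)
    sigma_x = np.sqrt(np.maximum(1.0 - pve, 0.0) / (cfg.n_exposure * het))

    alpha = np.zeros(J)
    n_pleio = int(round(cfg.pleiotropy_frac * J))
    if n_pleio > 0:
        idx = rng.choice(J, size=n_pleio, replace=False)
        alpha[idx] = rng.normal(cfg.pleiotropy_mean, cfg.pleiotropy_sd, size=n_pleio)

    cf = cfg.case_fraction
    sigma_y = 1.0 / np.sqrt(cfg.n_outcome * cf * (1.0 - cf) * het)
    Gamma = cfg.theta * gamma + alpha

    gamma_hat = rng.normal(gamma, sigma_x)
    Gamma_hat = rng.normal(Gamma, sigma_y)

    ids = [f"rs{j + 1}" for j in range(J)]
    exposure = _make_table(ids, maf, gamma_hat, sigma_x, cfg.n_exposure, "sim_exposure", TraitType.continuous)
    outcome = _make_table(ids, maf, Gamma_hat, sigma_y, cfg.n_outcome, "sim_outcome", TraitType.binary)
    truth = TwoSampleTruth(cfg.theta, maf, gamma, alpha, sigma_x, sigma_y, cfg.seed)
    return exposure, outcome, truth


def _maternal_effects(cfg: SimulationConfig, gamma: np.ndarray, het: np.ndarray, rng) -> np.ndarray:
    """Per-allele maternal effects with partial sign concordance to fetal effects.

    A fixed fraction (1 + rho) / 2 of the instruments (rounded; chosen at
    random) get maternal effects concordant in sign with their fetal effects,
    the rest discordant, so every simulated world carries the same net
    maternal-fetal alignment rho rather than a binomially noisy one.
    """
    J = len(gamma)
    mpve = cfg.maternal_pve_vector()
    mag = np.sqrt(mpve / het)
    rho = cfg.maternal_fetal_sign_concordance
    n_concordant = int(round((1.0 + rho) / 2.0 * J))
    signs = -np.ones(J)
    signs[rng.permutation(J)[:n_concordant]] = 1.0
    base = np.where(np.sign(gamma) == 0, 1.0, np.sign(gamma))
    return mag * signs * base


def simulate_mother_child(
    cfg: SimulationConfig,
    n_individuals: int,
    rng: np.random.Generator | None = None,
) -> MotherChildCohort:
    """Individual-level mother-child cohort under ``cfg``.

    Mother genotypes are Binomial(2, maf); the child receives one allele
    transmitted from the mother (uniformly among her two) plus one population
    allele at the same frequency, giving mother-child genotype correlation
    1/2.  Birth weight is x = sum_j gamma_j G_child,j + sum_j vartheta_j
    G_mother,j + e with e scaled so the *fetal-only* world has unit variance
    (maternal effects add variance on top of that baseline).  Disease is
    Bernoulli with logit = b0 + theta * x + maternal_direct_effect *
    (standardized maternal score); the direct maternal path is the
    config switch that induces genuine confounding.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    J = cfg.n_snps
    pve = cfg.pve_vector()
    maf = rng.uniform(cfg.maf_range[0], cfg.maf_range[1], size=J)
    het = 2.0 * maf * (1.0 - maf)
    signs = rng.choice([-1.0, 1.0], size=J) if cfg.gamma_sign == "random" else np.ones(J)
    gamma = signs * np.sqrt(pve / het)
    vartheta = _maternal_effects(cfg, gamma, het, rng)

    resid_var = 1.0 - float(np.sum(pve))
    if resid_var <= 0:
        raise ValueError("infeasible variance budget: total fetal PVE >= 1")

    g_mother = rng.binomial(2, maf, size=(n_individuals, J))
    transmitted = rng.binomial(1, g_mother / 2.0)
    population = rng.binomial(1, maf, size=(n_individuals, J))
    g_child = transmitted + population

    x = (
        g_child @ gamma
        + g_mother @ vartheta
        - 2.0 * (maf @ gamma)
        - 2.0 * (maf @ vartheta)
        + rng.normal(0.0, math.sqrt(resid_var), size=n_individuals)
    )

    logit = math.log(cfg.case_fraction / (1.0 - cfg.case_fraction)) + cfg.theta * x
    if cfg.maternal_direct_effect != 0.0:
        m_score = (g_mother - 2.0 * maf) @ vartheta
        sd = np.std(m_score)
        if sd > 0:
            logit = logit + cfg.maternal_direct_effect * m_score / sd
    disease = rng.binomial(1, 1.0 / (1.0 + np.exp(-logit)))

    return MotherChildCohort(
        snp_ids=tuple(f"rs{j + 1}" for j in range(J)),
        maf=maf,
        maternal_genotypes=g_mother,
        child_genotypes=g_child,
        birth_weight=x,
        disease=disease,
        gamma=gamma,
        vartheta=vartheta,
        theta=cfg.theta,
        case_fraction=cfg.case_fraction,
        seed=cfg.seed,
    )


def paired_instruments(exposure: SummaryStatsTable, outcome: SummaryStatsTable):
    """Zip two same-strand tables into harmonized instruments by snp_id.

    Intended for synthetic worlds where both tables are generated on the
    same strand with identical effect alleles, so the palindromic-ambiguity
    drop rule of :func:`bwmr.summary_io.harmonize` does not apply.  Real
    data should go through :func:`bwmr.summary_io.harmonize_tables`.
    """
    from .summary_io import HarmonizedInstrument

    out = []
    for e in exposure:
        o = outcome.get(e.snp_id)
        if o is None:
            continue
        if (o.effect_allele, o.other_allele) != (e.effect_allele, e.other_allele):
            raise ValueError(f"{e.snp_id}: paired_instruments requires identical alleles")
        out.append(HarmonizedInstrument(e.snp_id, e.beta, e.se, o.beta, o.se))
    return out


def table1_world(
    theta: float,
    n_outcome: int = 184_305,
    case_fraction: float = 0.33,
    seed: int = 0,
) -> tuple[SummaryStatsTable, SummaryStatsTable]:
    """Outcome-side simulation with the packaged 47-SNP table as the exposure.

    The printed per-SNP (beta, se, eaf, n) are used verbatim on the exposure
    side and treated as the true effects; only the outcome side is drawn:
    Gamma_hat_j ~ N(theta * beta_j, sigma_yj) with the binary-outcome
    score-test SE.  Defaults for the outcome sample match a large CAD GWAS
    (about 60k cases in 184k samples).
    """
    rng = np.random.default_rng(seed)
    exposure = load_table1_fixture()
    beta = np.array([r.beta for r in exposure])
    eaf = np.array([r.eaf for r in exposure])
    het = 2.0 * eaf * (1.0 - eaf)
    sigma_y = 1.0 / np.sqrt(n_outcome * case_fraction * (1.0 - case_fraction) * het)
    Gamma_hat = rng.normal(theta * beta, sigma_y)
    ids = [r.snp_id for r in exposure]
    outcome = _make_table(ids, eaf, Gamma_hat, sigma_y, n_outcome, "sim_disease", TraitType.binary)
    # outcome must carry the exposure's alleles so harmonization is identity
    fixed = [
        SnpAssociation(
            snp_id=o.snp_id,
            chrom=e.chrom,
            pos=e.pos,
            effect_allele=e.effect_allele,
            other_allele=e.other_allele,
            eaf=o.eaf,
            beta=o.beta,
            se=o.se,
            pval=o.pval,
            n=o.n,
        )
        for e, o in zip(exposure, outcome)
    ]
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        outcome = SummaryStatsTable(fixed, trait_label="sim_disease", trait_type=TraitType.binary)
    return exposure, outcome
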