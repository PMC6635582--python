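import math

import numpy as np
import pytest
from hypothesis import settings

# property tests check exact mathematical invariants; derandomize for
# reproducible runs
settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from bwmr.summary_io import (
    HarmonizedInstrument,
    SnpAssociation,
    SummaryStatsTable,
    TraitType,
    load_table1_fixture,
    load_table1_frame,
)


@pytest.fixture(scope="session")
def table1():
    return load_table1_fixture()


@pytest.fixture(scope="session")
def table1_frame():
    return load_table1_frame()


def make_snp(snp_id="rs1", chrom="1", pos=100, ea="T", oa="C", eaf=0.3,
             beta=-0.05, se=0.01, pval=None, n=100_000):
    if pval is None:
        from scipy.stats import norm

        pval = max(2 * norm.sf(abs(beta) / se), 1e-300)
    return SnpAssociation(snp_id, chrom, pos, ea, oa, eaf, beta, se, pval, n)


@pytest.fixture
def snp_factory():
    return make_snp


def random_instruments(rng, J=10, theta=0.3):
    """Generic harmonized-instrument sets for oracle comparisons."""
    g = rng.uniform(0.02, 0.2, J) * rng.choice([-1, 1], J)
    sx = rng.uniform(0.002, 0.01, J)
    sy = rng.uniform(0.005, 0.05, J)
    G = theta * g + rng.normal(0, sy)
    return [
        HarmonizedInstrument(f"rs{j}", float(g[j]), float(sx[j]), float(G[j]), float(sy[j]))
        for j in range(J)
    ]


@pytest.fixture
def instrument_factory():
    return random_instruments
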