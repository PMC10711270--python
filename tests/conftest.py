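import numpy as np
import pytest

from mrbodycomp import (
    AssociationRecord,
    HarmonizedInstrumentSet,
    SimulationConfig,
    SumStats,
    VariantKey,
    harmonize_sets,
    simulate_sumstats,
)

ALLELE_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C")]


def make_variant(i, chrom="1", ea=None, oa=None, pos=None):
    if ea is None:
        ea, oa = ALLELE_PAIRS[i % len(ALLELE_PAIRS)]
    return VariantKey(f"rs{i}", chrom, pos or (1000 + i * 100000), ea, oa)


def make_hset(bx, sx, by, sy, n_exp=100000.0, n_out=100000.0, eaf=None):
    """Harmonized set straight from arrays, bypassing file I/O."""
    n = len(bx)
    return HarmonizedInstrumentSet(
        "exp", "out", [make_variant(i) for i in range(n)],
        bx, sx, by, sy,
        eaf=eaf,
        n_exp=np.full(n, n_exp), n_out=np.full(n, n_out),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_hset(rng):
    """Factory for random harmonized sets of a given size."""

    def _make(n, seed=None):
        r = np.random.default_rng(seed) if seed is not None else rng
        bx = r.normal(0.05, 0.02, n)
        bx[bx == 0] = 0.01
        return make_hset(
            bx=bx,
            sx=r.uniform(0.002, 0.01, n),
            by=r.normal(0.01, 0.02, n),
            sy=r.uniform(0.002, 0.01, n),
        )

    return _make


@pytest.fixture
def clean_pair():
    """A pleiotropy-free simulated exposure/outcome pair and its truth."""
    return simulate_sumstats(SimulationConfig(n_snps=50, seed=42))


@pytest.fixture
def clean_hset(clean_pair):
    exp, out, _ = clean_pair
    hset, _ = harmonize_sets(exp, out)
    return hset


def make_record(v, beta=0.05, se=0.01, pval=1e-9, eaf=0.3, n=100000.0):
    return AssociationRecord(v, beta, se, pval, eaf=eaf, n=n)


def make_sumstats(records, name="trait", role="exposure", n_default=None):
    return SumStats(name, role, records, n_default=n_default)
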