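import numpy as np
import pytest

from sweepscan.variants_io import GenotypeTable, MISSING


def make_table(geno, positions=None, chrom="chr1", dp=30.0, mq=60.0, samples=None):
    """GenotypeTable from a (sites × samples) dosage array (-1 = missing)."""
    geno = np.asarray(geno, dtype=np.int8)
    n_sites, n_samples = geno.shape
    if positions is None:
        positions = np.arange(n_sites) * 100 + 50
    if samples is None:
        samples = [f"s{i}" for i in range(n_samples)]
    return GenotypeTable(
        samples, [chrom] * n_sites, positions,
        ["A"] * n_sites, ["T"] * n_sites,
        np.full(n_sites, dp, dtype=float), np.full(n_sites, mq, dtype=float),
        geno,
    )


def random_fixture(rng, max_samples=20, max_sites=50, missing_rate=0.05):
    """Random diploid fixture with two groups and some missing calls."""
    n_samples = int(rng.integers(6, max_samples + 1))
    n_sites = int(rng.integers(5, max_sites + 1))
    geno = rng.integers(0, 3, size=(n_sites, n_samples)).astype(np.int8)
    miss = rng.random((n_sites, n_samples)) < missing_rate
    geno[miss] = MISSING
    split = int(rng.integers(3, n_samples - 2))
    table = make_table(geno)
    group1 = table.samples[:split]
    group2 = table.samples[split:]
    return table, group1, group2


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def six_site_filter_table():
    """Six sites each violating exactly one quality criterion, plus one pass.

    10 samples.  Order: DP=4 (low), DP=150 (high), MQ=10, maf 0.05 (one het
    among ten diploids), missing 0.2, and a clean passing site.
    """
    n = 10
    common = np.array([0] * 5 + [1] * 3 + [2] * 2, dtype=np.int8)  # maf 0.35
    rare = np.array([1] + [0] * 9, dtype=np.int8)                  # maf 0.05
    missing2 = common.copy()
    missing2[:2] = MISSING                                         # miss 0.2
    geno = np.stack([common, common, common, rare, missing2, common])
    table = make_table(geno)
    table.dp[:] = [4, 150, 30, 30, 30, 30]
    table.mq[:] = [60, 60, 10, 60, 60, 60]
    return table
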