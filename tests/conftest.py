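import numpy as np
import pytest

from poolsweep.counts_io import SiteCountTable


def random_count_table(rng, n_sites=100, n_pools=3, chrom="chr1", max_count=60):
    """A random but valid count table with sorted, unique positions."""
    pos = np.sort(rng.choice(np.arange(1, 20 * n_sites), size=n_sites, replace=False))
    counts = rng.integers(0, max_count, size=(n_sites, n_pools, 6))
    ref = np.array(list("ACGT"))[rng.integers(0, 4, size=n_sites)].astype(object)
    return SiteCountTable(
        np.full(n_sites, chrom, dtype=object), pos, ref, counts,
        [f"pool{j}" for j in range(n_pools)],
    )


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


def two_pool_table(rows, pool_ids=("P1", "P2"), chrom="chr1"):
    """Build a table from (pos, ref, counts_pool1, counts_pool2) tuples,
    counts given as dicts like {"A": 30, "T": 2}."""
    order = ["A", "T", "C", "G", "N", "del"]
    pos, ref, counts = [], [], []
    for p, r, *pools in rows:
        pos.append(p)
        ref.append(r)
        counts.append([[d.get(b, 0) for b in order] for d in pools])
    n = len(pos)
    return SiteCountTable(
        np.full(n, chrom, dtype=object),
        np.array(pos), np.array(ref, dtype=object),
        np.array(counts), list(pool_ids),
    )
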