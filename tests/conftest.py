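import numpy as np
import pytest

from clonalscape.genotype_io import GenotypeTable


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_table(calls, site_ids=None, sample_ids=None, loci=None):
    """Small helper: build a GenotypeTable from a nested call list.

    ``calls`` is [[(a, b), ...] per sample]; use (0, 0) for missing.
    """
    calls = np.asarray(calls, dtype=np.int64)
    n, L = calls.shape[:2]
    return GenotypeTable(
        sample_ids or [f"s{i+1:02d}" for i in range(n)],
        site_ids or ["siteA"] * n,
        loci or [f"loc{j+1}" for j in range(L)],
        calls,
    )


def hwe_table(freq_list, n_per_pop, k_pops, rng, pop_prefix="p"):
    """Independent HWE draws from shared allele frequencies, k populations."""
    L = len(freq_list)
    n = n_per_pop * k_pops
    calls = np.empty((n, L, 2), dtype=np.int64)
    for j, p in enumerate(freq_list):
        calls[:, j, :] = rng.choice(np.arange(1, p.size + 1), size=(n, 2), p=p)
    calls = np.sort(calls, axis=2)
    pops = [f"{pop_prefix}{i // n_per_pop}" for i in range(n)]
    return GenotypeTable([f"s{i}" for i in range(n)], pops,
                         [f"l{j}" for j in range(L)], calls), np.array(pops)
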