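import numpy as np
import pandas as pd
import pytest

from mrmediate.sumstats import HarmonizedPairs, SumStats


def make_sumstats(rows, label="trait"):
    """Build a SumStats from (snp_id, chrom, pos, ea, oa, eaf, beta, se, pval, n) tuples."""
    cols = ["snp_id", "chrom", "pos", "effect_allele", "other_allele",
            "eaf", "beta", "se", "pval", "n"]
    return SumStats(label, pd.DataFrame(rows, columns=cols))


def snp_row(snp_id, beta, se, pval, chrom="1", pos=None, ea="A", oa="G",
            eaf=0.3, n=10000):
    if pos is None:
        pos = 1000 * (abs(hash(snp_id)) % 100000 + 1)
    return (snp_id, chrom, pos, ea, oa, eaf, beta, se, pval, n)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def random_pairs_factory(rng):
    """Random valid-instrument HarmonizedPairs for oracle comparisons."""

    def factory(n_snp=None, with_mediator=False, seed=None):
        r = np.random.default_rng(seed) if seed is not None else rng
        j = n_snp or int(r.integers(5, 30))
        bx = r.normal(0.05, 0.03, j)
        bx[bx == 0] = 0.01
        se_x = r.uniform(0.002, 0.01, j)
        se_y = r.uniform(0.002, 0.01, j)
        by = 0.4 * bx + r.normal(0, se_y)
        kw = {}
        if with_mediator:
            kw["beta_mediator"] = 0.3 * bx + r.normal(0, 0.005, j)
            kw["se_mediator"] = r.uniform(0.002, 0.01, j)
        return HarmonizedPairs.from_arrays(bx, se_x, by, se_y, **kw)

    return factory
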