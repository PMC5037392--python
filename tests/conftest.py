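import numpy as np
import pytest

from poolfilter.model import CallSet, PoolCounts, PoolVariant
from poolfilter.simdata import SimConfig, simulate_cohort


def make_variant(pos, qual, counts, in_db=False, chrom="1", ref="A", alt="G"):
    return PoolVariant(
        chrom=chrom, pos=pos, ref_allele=ref, alt_allele=alt, qual=qual,
        counts=tuple(PoolCounts(r, a) for r, a in counts), in_db=in_db,
    )


@pytest.fixture
def tiny_callset():
    """5 variants, 2 pools: 3 annotated (QUAL 50/60/70), 2 novel (QUAL 20/30)."""
    variants = [
        make_variant(100, 50.0, [(90, 10), (80, 20)], in_db=True),
        make_variant(200, 60.0, [(50, 50), (100, 0)], in_db=True),
        make_variant(300, 70.0, [(0, 40), (40, 0)], in_db=True),
        make_variant(400, 20.0, [(99, 1), (98, 2)], in_db=False),
        make_variant(500, 30.0, [(97, 3), (396, 4)], in_db=False),
    ]
    return CallSet(pool_size_n=12, variants=variants)


@pytest.fixture(scope="session")
def small_sim():
    """A down-scaled simulated cohort with ground truth (fast, deterministic)."""
    cfg = SimConfig(seed=2024, num_pools=20, num_true_variants=400,
                    num_error_sites=1600, region_length=500_000)
    cs, truth = simulate_cohort(cfg)
    return cfg, cs, truth


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(7)
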