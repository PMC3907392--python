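import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import bsmeth as b
from bsmeth.types import CytosineSite, GenomicInterval

settings.register_profile(
    "ci", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def toy_genome():
    return b.make_toy_genome(20_000, gc_frac=0.4, n_islands=2, island_len=300, seed=1)


@pytest.fixture(scope="session")
def toy_truth():
    return b.TruthModel(seed=1)


def make_cg_sites(chrom, positions, levels, depth, rng, context="CG", strand="+"):
    """Site list with binomially sampled counts at the given true levels."""
    sites = []
    for pos, lvl in zip(positions, levels):
        m = int(rng.binomial(depth, lvl))
        sites.append(CytosineSite(chrom, int(pos), strand, context, m, depth))
    return sites


@pytest.fixture
def planted_dmr_sites():
    """Two samples: identical 0.5 background, one 50-CG region at 0.9 vs 0.1."""
    rng = np.random.default_rng(11)
    background = np.arange(0, 20_000, 40)
    planted = np.arange(8_000, 9_000, 20)
    pos = np.unique(np.concatenate([background, planted]))
    in_planted = (pos >= 8_000) & (pos < 9_000)
    lv_a = np.where(in_planted, 0.9, 0.5)
    lv_b = np.where(in_planted, 0.1, 0.5)
    a = make_cg_sites("chrD", pos, lv_a, 20, rng)
    b_ = make_cg_sites("chrD", pos, lv_b, 20, rng)
    region = GenomicInterval("chrD", 8_000, 9_000)
    return a, b_, region
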