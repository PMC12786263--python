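import numpy as np
import pytest

from invamp import simulate as sim


@pytest.fixture(scope="session")
def locus_hap():
    """Small chromosome with a multicopy locus: copies 1,1,1,1,7,7,7,35."""
    loc = sim.LocusSpec(
        position=50_000, flank_left_len=1200, flank_right_len=1000,
        unit_length=630,
        units_per_copy_wildtype=[1],
        units_per_copy_rearranged=[1, 1, 1, 1, 7, 7, 7, 35],
    )
    cfg = sim.SimConfig(chromosome_length=100_000, locus=loc, seed=11)
    hap, truth = sim.build_haplotypes(cfg)
    return cfg, hap, truth


@pytest.fixture(scope="session")
def collapsed_block_hap():
    """One collapsed 6 kb block at 10 (wild) vs 1 (rearranged) per homolog."""
    blk = sim.CNVBlock(id="CNV7", position=120_000, unit_length=6000,
                       copies_wildtype=10, copies_rearranged=1)
    cfg = sim.SimConfig(chromosome_length=300_000, cnv_blocks=[blk], seed=21)
    hap, truth = sim.build_haplotypes(cfg)
    return cfg, hap, truth


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(0)
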