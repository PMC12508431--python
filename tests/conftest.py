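import numpy as np
import pytest

from enhquant.regions import EnhancerLocus, GenomicInterval
from enhquant.spikenorm import ReadSet
from enhquant.synthdata import SimConfig, generate_annotation


@pytest.fixture(scope="session")
def tiny_cfg() -> SimConfig:
    """Small study: 60 loci on a 12 Mb chromosome, fast to simulate."""
    return SimConfig(
        seed=11,
        n_enhancers=60,
        target_chrom_length=12_000_000,
        n_null_genes=50,
    )


@pytest.fixture(scope="session")
def tiny_annotation(tiny_cfg):
    return generate_annotation(tiny_cfg)


@pytest.fixture
def simple_locus() -> EnhancerLocus:
    return EnhancerLocus(id="E1", interval=GenomicInterval("chr1", 150, 700))


def make_readset(sample_id, triples, spike_prefix="dm6_", names=None) -> ReadSet:
    """Build a ReadSet from (chrom, start, end) triples."""
    chroms = [t[0] for t in triples]
    starts = [t[1] for t in triples]
    ends = [t[2] for t in triples]
    return ReadSet.from_arrays(sample_id, chroms, starts, ends, spike_prefix, names=names)


def random_reads(rng, n, chrom="chr1", max_coord=10_000, max_len=80):
    starts = rng.integers(0, max_coord, size=n)
    lengths = rng.integers(1, max_len, size=n)
    return [(chrom, int(s), int(s + l)) for s, l in zip(starts, lengths)]
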