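import dataclasses

import numpy as np
import pytest

from epiregulome.intervals import GeneModel, GenomicInterval
from epiregulome.simulate import SimConfig, default_cna_segments, simulate_genome


@pytest.fixture(scope="session")
def small_cfg() -> SimConfig:
    """Desk-scale default study design with its standard CN segments."""
    cfg = SimConfig(seed=11)
    return dataclasses.replace(cfg, cna_segments=default_cna_segments(cfg))


@pytest.fixture(scope="session")
def small_genome(small_cfg):
    return simulate_genome(small_cfg)


def random_intervals(rng: np.random.Generator, n: int, chroms=("chr1", "chr2"),
                     max_pos: int = 100_000, max_len: int = 5_000):
    out = []
    for _ in range(n):
        chrom = chroms[rng.integers(len(chroms))]
        start = int(rng.integers(0, max_pos))
        length = int(rng.integers(1, max_len))
        out.append(GenomicInterval(chrom, start, start + length))
    return out


def random_genes(rng: np.random.Generator, n: int, chroms=("chr1", "chr2"),
                 max_pos: int = 100_000):
    out = []
    for i in range(n):
        chrom = chroms[rng.integers(len(chroms))]
        start = int(rng.integers(0, max_pos))
        length = int(rng.integers(500, 10_000))
        strand = "+" if rng.random() < 0.5 else "-"
        biotype = "protein_coding" if rng.random() < 0.8 else "lincRNA"
        out.append(GeneModel(f"g{i:03d}", GenomicInterval(chrom, start, start + length),
                             strand, biotype))
    return out
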