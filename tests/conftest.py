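import numpy as np
import pandas as pd
import pytest

from methcanyon.config import SimConfig
from methcanyon.simulate import simulate_all
from methcanyon.tracks import ChromSites, MethTrack


def small_config(**overrides) -> SimConfig:
    """A fast single-chromosome configuration for unit tests."""
    base = dict(n_chroms=1, chrom_length=400_000, n_genes=40, n_cgis=18,
                n_enhancers=10, n_canyons=6, coverage_mean=20.0,
                n_replicates=2, seed=7)
    base.update(overrides)
    return SimConfig(**base)


@pytest.fixture(scope="session")
def sim_small():
    return simulate_all(small_config())


def make_track(sites, sample="t", genotype="WT"):
    """Build a MethTrack from {chrom: [(pos, m, u), ...]}."""
    chroms = {}
    for chrom, recs in sites.items():
        recs = sorted(recs)
        pos = np.array([r[0] for r in recs], dtype=np.int64)
        m = np.array([r[1] for r in recs], dtype=np.int64)
        u = np.array([r[2] for r in recs], dtype=np.int64)
        chroms[chrom] = ChromSites(pos, m, u)
    return MethTrack(sample=sample, genotype=genotype, chroms=chroms)


def uniform_track(chrom, start, end, spacing, level, coverage=100,
                  sample="t", genotype="WT"):
    """Evenly spaced CpGs with exact (deterministic) counts at `level`."""
    pos = np.arange(start, end, spacing)
    m = int(round(level * coverage))
    return make_track({chrom: [(int(p), m, coverage - m) for p in pos]},
                      sample=sample, genotype=genotype)


@pytest.fixture
def gene_plus():
    return pd.Series({"gene_id": "gA", "chrom": "chr1", "start": 10_000,
                      "end": 20_000, "strand": "+", "tss": 10_000,
                      "tts": 20_000})


@pytest.fixture
def gene_minus():
    return pd.Series({"gene_id": "gB", "chrom": "chr1", "start": 10_000,
                      "end": 20_000, "strand": "-", "tss": 20_000,
                      "tts": 10_000})
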