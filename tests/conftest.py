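import numpy as np
import pytest

from pausekit.coverage import CoverageTrack
from pausekit.intervals import GeneAnnotation, GenomicInterval


def make_track(values, bin_size=50, chrom="chr1", length=None):
    """CoverageTrack from a plain list of bin values on one chromosome."""
    v = np.asarray(values, dtype=float)
    if length is None:
        length = v.size * bin_size
    return CoverageTrack(
        bin_size=bin_size, chrom_lengths={chrom: length}, values={chrom: v}
    )


def make_gene(gene_id="g1", start=1000, end=6000, strand="+", chrom="chr1"):
    return GeneAnnotation(gene_id, GenomicInterval(chrom, start, end), strand)


@pytest.fixture
def flat_track():
    """Uniform signal 2.0 over a 100-kb chromosome (50-bp bins)."""
    return make_track([2.0] * 2000)


@pytest.fixture
def small_sim():
    """A small (150-gene) synthetic dataset shared across tests."""
    from pausekit.simulate import SimConfig, simulate_genome

    cfg = SimConfig(n_genes=150, chrom_length=4_000_000, seed=7)
    genes, truth = simulate_genome(cfg)
    return cfg, genes, truth
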