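import numpy as np
import pytest

from epigerm.genomics import GeneModel, GenomicInterval
from epigerm.synthetic import SimConfig, make_genome


@pytest.fixture(scope="session")
def small_config():
    """A compact world for unit tests (single chromosome, fast)."""
    return SimConfig(seed=7, n_chrom=1, chrom_length=400_000, n_genes=40,
                     n_tf_sites=10, n_repeat_instances=10, n_de_up=8, n_de_down=4)


@pytest.fixture(scope="session")
def small_truth(small_config):
    return make_genome(small_config)


@pytest.fixture
def toy_genes():
    """Two genes on chr1: g_plus at [10_000, 20_000) '+' and g_minus at
    [40_000, 50_000) '-'; each with 3 exons of 500 bp."""
    def build(gene_id, start, end, strand):
        chrom = "chr1"
        e1 = GenomicInterval(chrom, start, start + 500, strand)
        mid = (start + end) // 2
        e2 = GenomicInterval(chrom, mid, mid + 500, strand)
        e3 = GenomicInterval(chrom, end - 500, end, strand)
        return GeneModel(gene_id, gene_id, GenomicInterval(chrom, start, end, strand),
                         strand, exons=(e1, e2, e3))

    return [build("g_minus", 40_000, 50_000, "-"), build("g_plus", 10_000, 20_000, "+")]
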