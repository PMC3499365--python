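import numpy as np
import pytest

from lncstab.genome import GeneCatalog, GeneRecord


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)


def make_gene(gene_id, chrom, start, end, strand="+", exons=None, **kw):
    exons = exons or [(start, end)]
    return GeneRecord(gene_id=gene_id, source=kw.pop("source", "test"),
                      chrom=chrom, strand=strand, isoforms=[list(exons)], **kw)


def make_catalog(*records):
    cat = GeneCatalog()
    for rec in records:
        cat.add(rec)
    return cat


@pytest.fixture
def random_catalog(rng):
    """A catalog of random single-isoform genes for oracle comparisons."""
    def build(n, chrom_len=1_000_000, chroms=("c1", "c2"), seed=None):
        local = np.random.default_rng(seed) if seed is not None else rng
        cat = GeneCatalog()
        for i in range(n):
            chrom = chroms[int(local.integers(len(chroms)))]
            start = int(local.integers(0, chrom_len - 10_000))
            length = int(local.integers(100, 10_000))
            strand = "+" if local.random() < 0.5 else "-"
            cat.add(make_gene(f"g{i:04d}", chrom, start, start + length, strand))
        return cat
    return build
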