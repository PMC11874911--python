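import numpy as np
import pandas as pd
import pytest

from txchromdyn.genome_model import GeneModel, GenomicInterval


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_gene(gene_id="g0", chrom="chr1", strand="+", start=10_000, end=20_000):
    return GeneModel(gene_id, chrom, strand, start, end)


def random_genes(rng, n, chrom="chr1", min_len=3000, max_len=30_000,
                 genome_span=5_000_000):
    genes = []
    for i in range(n):
        start = int(rng.integers(10_000, genome_span))
        length = int(rng.integers(min_len, max_len))
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(GeneModel(f"g{i:04d}", chrom, strand, start, start + length))
    return genes


def random_intervals(rng, n, chrom="chr1", span=5_000_000, min_len=50, max_len=2000):
    out = []
    for _ in range(n):
        s = int(rng.integers(0, span))
        out.append(GenomicInterval(chrom, s, s + int(rng.integers(min_len, max_len))))
    return out


def reads_df(chrom, starts, ends):
    return pd.DataFrame({"chrom": chrom, "start": starts, "end": ends})
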