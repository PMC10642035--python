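import numpy as np
import pandas as pd
import pytest

from oxbsdm.io import SiteCalls


@pytest.fixture
def make_calls():
    """Factory for small SiteCalls tables from (pos, coverage, modified) triples."""

    def _make(rows, context="CG", chrom="chr1", strand="+"):
        pos, cov, mod = zip(*rows)
        strands = [strand] * len(pos) if isinstance(strand, str) else list(strand)
        return SiteCalls.from_arrays([chrom] * len(pos), pos, strands, cov, mod, context)

    return _make


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def simple_genes():
    """Two genes on opposite strands with exon/CDS structure, 100 kb apart."""
    return pd.DataFrame(
        [
            dict(gene_id="gA", chrom="chr1", strand="+", start=10_000, end=20_000,
                 exon_starts=[10_000, 13_000, 17_000], exon_ends=[11_000, 14_000, 20_000],
                 cds_start=10_500, cds_end=18_500),
            dict(gene_id="gB", chrom="chr1", strand="-", start=120_000, end=130_000,
                 exon_starts=[120_000, 124_000, 128_000], exon_ends=[121_000, 125_000, 130_000],
                 cds_start=120_500, cds_end=129_500),
        ]
    )
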