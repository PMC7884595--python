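import numpy as np
import pytest

from evomap.structures import GeneRecord, SprinzlMap, StructuralAlignment


def make_gene(gene_id, cls, seq=None, width=74, **kw):
    """A GeneRecord with a sequence padded/truncated to the alignment width."""
    seq = (seq or "") + "A" * width
    return GeneRecord(gene_id=gene_id, aligned_seq=seq[:width],
                      functional_class=cls, **kw)


def make_alignment(rows, width=74):
    """Build a StructuralAlignment from (gene_id, class, seq_prefix) tuples."""
    genes = [make_gene(gid, cls, seq, width=width) for gid, cls, seq in rows]
    return StructuralAlignment(genes, width=width)


@pytest.fixture
def sprinzl():
    return SprinzlMap()


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)
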