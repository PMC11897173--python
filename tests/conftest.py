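import numpy as np
import pytest

from ganopan.io_formats import GeneModel, Transcript
from ganopan.pangenome import OrthogroupMatrix


def make_gene(gene_id="g1", chrom="chr1", strand="+", start=1000,
              utr=30, cds1=90, intron=60, cds2=120):
    """Two-exon gene: [UTR+CDS1] - intron - [CDS2+UTR]."""
    e1 = (start, start + utr + cds1)
    c1 = (start + utr, start + utr + cds1)
    i0 = e1[1]
    e2 = (i0 + intron, i0 + intron + cds2 + utr)
    c2 = (i0 + intron, i0 + intron + cds2)
    return GeneModel(gene_id, chrom, strand, start, e2[1],
                     [Transcript(f"{gene_id}.t1", [e1, e2], [c1, c2])])


def matrix_from_presence(presence, genomes=None):
    """OrthogroupMatrix from a dict family -> set of genome ids."""
    if genomes is None:
        genomes = sorted({g for s in presence.values() for g in s})
    fams = sorted(presence)
    gc = np.array([[1 if g in presence[f] else 0 for g in genomes]
                   for f in fams])
    return OrthogroupMatrix(tuple(fams), tuple(genomes), gc)


@pytest.fixture
def two_exon_gene():
    return make_gene()


@pytest.fixture
def toy_matrix3():
    """3 genomes, families: f1 in all, f2 in A only, f3 in B,C."""
    return matrix_from_presence({
        "f1": {"A", "B", "C"}, "f2": {"A"}, "f3": {"B", "C"},
    })
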