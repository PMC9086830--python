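import pytest

from apakit.annotation import load_annotation
from apakit.synthetic import SimDesign, simulate_genome, simulate_tags

# Two genes on chr1 ('+' with an annotated 3'UTR, '-' without one) and a
# two-isoform gene on chr2 whose isoforms stop at different codons.
TOY_GFF3 = """##gff-version 3
##sequence-region chr1 1 10000
##sequence-region chr2 1 10000
chr1\ttoy\tgene\t101\t1000\t.\t+\t.\tID=geneA
chr1\ttoy\tmRNA\t101\t1000\t.\t+\t.\tID=geneA.1;Parent=geneA
chr1\ttoy\texon\t101\t1000\t.\t+\t.\tID=geneA.1.e1;Parent=geneA.1
chr1\ttoy\tCDS\t151\t782\t.\t+\t.\tID=geneA.1.c;Parent=geneA.1
chr1\ttoy\tthree_prime_UTR\t783\t1000\t.\t+\t.\tID=geneA.1.u3;Parent=geneA.1
chr1\ttoy\tgene\t3001\t3600\t.\t-\t.\tID=geneB
chr1\ttoy\tmRNA\t3001\t3600\t.\t-\t.\tID=geneB.1;Parent=geneB
chr1\ttoy\texon\t3001\t3600\t.\t-\t.\tID=geneB.1.e1;Parent=geneB.1
chr1\ttoy\tCDS\t3001\t3550\t.\t-\t.\tID=geneB.1.c;Parent=geneB.1
chr2\ttoy\tgene\t501\t2000\t.\t+\t.\tID=geneC
chr2\ttoy\tmRNA\t501\t1500\t.\t+\t.\tID=geneC.1;Parent=geneC
chr2\ttoy\texon\t501\t1500\t.\t+\t.\tID=geneC.1.e1;Parent=geneC.1
chr2\ttoy\tCDS\t601\t1200\t.\t+\t.\tID=geneC.1.c;Parent=geneC.1
chr2\ttoy\tmRNA\t501\t2000\t.\t+\t.\tID=geneC.2;Parent=geneC
chr2\ttoy\texon\t501\t2000\t.\t+\t.\tID=geneC.2.e1;Parent=geneC.2
chr2\ttoy\tCDS\t601\t1500\t.\t+\t.\tID=geneC.2.c;Parent=geneC.2
"""

# geneA: 0-based exon [100,1000), CDS [150,782), utr3 [782,1000) -> 218 nt.
# geneB: '-' strand, CDS [3000,3550), no annotated 3'UTR (stop at 3000).
# geneC: isoform stops at 1200 and 1500 -> collapsed cds_end = 1500.


@pytest.fixture
def toy_gff3():
    return TOY_GFF3


@pytest.fixture
def toy_catalog():
    return load_annotation(TOY_GFF3)


@pytest.fixture
def toy_catalog_extended():
    return load_annotation(TOY_GFF3).extend_all()


@pytest.fixture(scope="session")
def small_sim():
    """A small simulated dataset shared across tests (40 genes, 3+3 reps)."""
    design = SimDesign(n_genes=40, seed=11)
    gff3, truth = simulate_genome(design)
    tagsets = simulate_tags(truth, design)
    catalog = load_annotation(gff3, chrom_sizes=truth.chrom_sizes)
    catalog.extend_all()
    return design, truth, tagsets, catalog
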