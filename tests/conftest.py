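import pytest

from consanno.models import FeatureTypeMap, GenomeSequence
from consanno.simulate import six_gene_fixture

# 3 genes on a 120-nt contig; g2 has two isoforms sharing the first CDS.
# Hand-enumerated: 3 genes, isoform counts {g1: 1, g2: 2, g3: 1}.
THREE_GENE_GFF3 = """##gff-version 3
chr1\ttest\tgene\t1\t9\t.\t+\t.\tID=g1
chr1\ttest\tmRNA\t1\t9\t.\t+\t.\tID=g1.t1;Parent=g1
chr1\ttest\tCDS\t1\t9\t.\t+\t0\tID=c1;Parent=g1.t1
chr1\ttest\tgene\t21\t50\t.\t+\t.\tID=g2
chr1\ttest\tmRNA\t21\t50\t.\t+\t.\tID=g2.t1;Parent=g2
chr1\ttest\tCDS\t21\t32\t.\t+\t0\tID=c2;Parent=g2.t1
chr1\ttest\tCDS\t42\t50\t.\t+\t0\tID=c2;Parent=g2.t1
chr1\ttest\tmRNA\t21\t32\t.\t+\t.\tID=g2.t2;Parent=g2
chr1\ttest\tCDS\t21\t32\t.\t+\t0\tID=c3;Parent=g2.t2
chr1\ttest\tgene\t61\t72\t.\t-\t.\tID=g3
chr1\ttest\tmRNA\t61\t72\t.\t-\t.\tID=g3.t1;Parent=g3
chr1\ttest\tCDS\t61\t72\t.\t-\t0\tID=c4;Parent=g3.t1
"""


@pytest.fixture(scope="session")
def tiny_genome():
    # g1: ATGAAATAA (MK); g2.t1 spans [20,32)+[41,50); g3 minus strand
    seq = list("A" * 120)
    seq[0:9] = "ATGAAATAA"
    seq[20:32] = "ATGGCCGCCGCA"      # M A A A ...
    seq[41:50] = "GCCAAATAA"          # ... A K *
    seq[60:72] = "TTACTTGGCCAT"       # revcomp -> ATGGCCAAGTAA = M A K *
    return GenomeSequence({"chr1": "".join(seq)})


@pytest.fixture
def three_gene_annotation(tiny_genome):
    from consanno.annotation_io import parse_gff3

    return parse_gff3(THREE_GENE_GFF3, FeatureTypeMap.default(),
                      source_name="test")


@pytest.fixture(scope="session")
def demo():
    return six_gene_fixture()


@pytest.fixture(scope="session")
def demo_consensus(demo):
    from consanno.orthology import SpeciesTree
    from consanno.pipeline import build_consensus

    tree = SpeciesTree.from_newick(demo.tree_newick, sorted(demo.annotations))
    return build_consensus(demo.genome, demo.annotations, tree, demo.outgroups)
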