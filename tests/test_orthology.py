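import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from oracles import sw_affine_bruteforce

from consanno.errors import DataError
from consanno.models import ProteinRecord, protein_id
from consanno.orthology import (
    AlignmentHit,
    EngineParams,
    ProteinDatabase,
    SpeciesTree,
    build_hogs,
    infer_ortholog_pairs,
    read_orthoxml,
    select_main_isoform,
    smith_waterman_score,
)

AA = "ACDEFGHIKLMNPQRSTVWY"


def rand_protein(rng, n):
    return "".join(AA[i] for i in rng.integers(0, 20, n))


def rec(species, gene, tx, seq):
    return ProteinRecord(protein_id(species, gene, tx), seq, species, gene, tx)


class TestSmithWaterman:
    def test_identity_score(self):
        assert smith_waterman_score("MKV", "MKV") == 14  # 5+5+4

    def test_empty_sequence(self):
        assert smith_waterman_score("MKV", "") == 0
        assert smith_waterman_score("", "") == 0

    def test_local_ignores_flanks(self):
        assert smith_waterman_score("AAAMKVAAA", "MKV") == 14

    def test_against_bruteforce_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(60):
            a = rand_protein(rng, int(rng.integers(1, 31)))
            b = rand_protein(rng, int(rng.integers(1, 31)))
            assert smith_waterman_score(a, b) == sw_affine_bruteforce(a, b)

    @given(st.text(alphabet=AA, min_size=0, max_size=15),
           st.text(alphabet=AA, min_size=0, max_size=15))
    @settings(max_examples=50, deadline=None)
    def test_symmetric_and_nonnegative(self, a, b):
        s = smith_waterman_score(a, b)
        assert s == smith_waterman_score(b, a)
        assert s >= 0

    def test_x_scores_zero(self):
        assert smith_waterman_score("XXXX", "XXXX") == 0


class TestSelectMainIsoform:
    def proteins(self):
        return [rec("s", "g", "tA", "MKVLW" * 10),
                rec("s", "g", "tB", "MKVLW" * 8)]

    def test_highest_summed_score_wins(self):
        pa, pb = self.proteins()
        hits = [AlignmentHit(pb.protein_id, "o|x|t", 20, 1.0),
                AlignmentHit(pa.protein_id, "o|x|t", 15, 1.0),
                AlignmentHit(pa.protein_id, "o|y|t", 15, 1.0)]
        # pa sums 30, pb sums 20
        assert select_main_isoform([pa, pb], hits) is pa

    def test_no_hits_falls_back_to_longest(self):
        pa, pb = self.proteins()
        assert select_main_isoform([pa, pb], []) is pa

    def test_tie_breaks_on_transcript_id(self):
        pa = rec("s", "g", "tA", "MKVLW" * 10)
        pb = rec("s", "g", "tB", "MKVLW" * 10)
        assert select_main_isoform([pb, pa], []) is pa

    def test_empty_is_error(self):
        with pytest.raises(DataError):
            select_main_isoform([], [])


class TestInferOrthologPairs:
    def test_identical_proteins_pair(self):
        rng = np.random.default_rng(0)
        seq = rand_protein(rng, 50)
        db = ProteinDatabase({"A": [rec("A", "g1", "t1", seq)],
                              "B": [rec("B", "h1", "t1", seq)]})
        assert infer_ortholog_pairs(db) == {("A|g1|t1", "B|h1|t1")}

    def test_below_min_score_no_pair(self):
        db = ProteinDatabase({"A": [rec("A", "g1", "t1", "MKV")],
                              "B": [rec("B", "h1", "t1", "MKV")]})
        assert infer_ortholog_pairs(db) == set()  # score 14 < 40

    def test_two_by_two_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(4)
        s1, s2 = rand_protein(rng, 60), rand_protein(rng, 60)

        def mutate(seq, k):
            out = list(seq)
            for i in rng.choice(len(seq), size=k, replace=False):
                out[i] = AA[(AA.index(out[i]) + 1) % 20]
            return "".join(out)

        a1, a2 = rec("A", "g1", "t", s1), rec("A", "g2", "t", s2)
        b1, b2 = rec("B", "h1", "t", mutate(s1, 5)), rec("B", "h2", "t", mutate(s2, 5))
        db = ProteinDatabase({"A": [a1, a2], "B": [b1, b2]})
        pairs = infer_ortholog_pairs(db)

        # oracle: exhaustive scoring with the brute-force DP, strict RBH
        scores = {(x.protein_id, y.protein_id):
                  sw_affine_bruteforce(x.sequence, y.sequence)
                  for x in (a1, a2) for y in (b1, b2)}
        expected = set()
        for x in (a1, a2):
            for y in (b1, b2):
                s = scores[(x.protein_id, y.protein_id)]
                if s < 40:
                    continue
                if s == max(scores[(x.protein_id, yy.protein_id)] for yy in (b1, b2)) \
                        and s == max(scores[(xx.protein_id, y.protein_id)] for xx in (a1, a2)):
                    expected.add((x.protein_id, y.protein_id))
        assert pairs == expected == {("A|g1|t", "B|h1|t"), ("A|g2|t", "B|h2|t")}

    def test_pairs_are_unordered_canonical(self):
        rng = np.random.default_rng(1)
        seq = rand_protein(rng, 50)
        db = ProteinDatabase({"Z": [rec("Z", "g", "t", seq)],
                              "A": [rec("A", "g", "t", seq)]})
        assert infer_ortholog_pairs(db) == {("A|g|t", "Z|g|t")}


TREE = "((s1,s2,s3)consensus,outA)root;"


def make_tree():
    return SpeciesTree.from_newick(TREE, ["s1", "s2", "s3"])


def small_db(rng):
    return ProteinDatabase({
        "s1": [rec("s1", "g1", "t", rand_protein(rng, 50))],
        "s2": [rec("s2", "g1p", "t", rand_protein(rng, 50))],
        "s3": [rec("s3", "g5", "t", rand_protein(rng, 50))],
        "outA": [rec("outA", "h", "t", rand_protein(rng, 50))],
    })


class TestSpeciesTree:
    def test_consensus_node_found(self):
        tree = make_tree()
        assert sorted(tree.consensus_node.leaf_names()) == ["s1", "s2", "s3"]
        assert tree.outgroups == ["outA"]

    def test_sources_missing_from_tree(self):
        with pytest.raises(Exception, match="absent"):
            SpeciesTree.from_newick(TREE, ["s1", "s2", "nope"])

    def test_lca(self):
        tree = make_tree()
        assert tree.lca(["s1", "s2"]) is tree.consensus_node
        assert tree.lca(["s1", "outA"]) is tree.root


class TestBuildHogs:
    def test_single_pair_one_hog(self):
        tree, db = make_tree(), small_db(np.random.default_rng(2))
        forest = build_hogs({("s1|g1|t", "s2|g1p|t")}, tree, db)
        consensus = forest.ancestral_genome()
        members = sorted(frozenset(h.members) for h in consensus)
        assert frozenset({("s1", "g1"), ("s2", "g1p")}) in members
        assert len(consensus) == 2  # the pair plus singleton g5

    def test_outgroup_pair_keeps_singleton_at_consensus(self):
        tree, db = make_tree(), small_db(np.random.default_rng(2))
        forest = build_hogs({("outA|h|t", "s3|g5|t")}, tree, db)
        g5_hog = next(h for h in forest.ancestral_genome()
                      if ("s3", "g5") in h.members)
        assert g5_hog.members == frozenset({("s3", "g5")})
        root_ancestors = list(g5_hog.ancestors())
        assert any(("outA", "h") in a.members for a in root_ancestors)

    def test_no_pairs_all_singletons(self):
        tree, db = make_tree(), small_db(np.random.default_rng(2))
        forest = build_hogs(set(), tree, db)
        for node in tree.postorder():
            if node.is_leaf:
                continue
            for hog in forest.hogs_at(node):
                assert len(hog.members) == 1

    def test_unknown_species_is_error(self):
        tree, db = make_tree(), small_db(np.random.default_rng(2))
        with pytest.raises(DataError):
            build_hogs({("s1|g1|t", "zz|q|t")}, tree, db)

    def test_nesting_and_partition_invariants(self):
        tree, db = make_tree(), small_db(np.random.default_rng(2))
        forest = build_hogs({("s1|g1|t", "s2|g1p|t"),
                             ("s3|g5|t", "outA|h|t")}, tree, db)
        for node in tree.postorder():
            hogs = forest.hogs_at(node)
            seen = set()
            for hog in hogs:
                assert not (hog.members & seen), "HOGs must partition genes"
                seen |= hog.members
                if hog.parent is not None:
                    assert hog.members <= hog.parent.members


def test_zero_divergence_copies_one_gene_per_source():
    # every gene copied identically into every source: each consensus HOG
    # holds exactly one gene per source
    from consanno.annotation_io import extract_proteome
    from consanno.simulate import SimulationConfig, derive_source_annotation, simulate_truth

    ts = simulate_truth(SimulationConfig(n_genes=12, seed=9))
    for name in ("s1", "s2", "s3"):
        derive_source_annotation(ts, name, seed=1)
    proteomes = {name: extract_proteome(ann, ts.genome).records
                 for name, ann in ts.sources.items()}
    db = ProteinDatabase(proteomes)
    tree = SpeciesTree.from_newick("((s1,s2,s3)consensus);", ["s1", "s2", "s3"])
    forest = build_hogs(infer_ortholog_pairs(db), tree, db)
    hogs = forest.ancestral_genome()
    assert len(hogs) == 12
    for hog in hogs:
        species = [sp for sp, _ in hog.members]
        assert sorted(species) == ["s1", "s2", "s3"]


MINIMAL_ORTHOXML = """<?xml version="1.0"?>
<orthoXML xmlns="http://orthoXML.org/2011/" version="0.3" origin="test" originVersion="1">
 <species name="s1" NCBITaxId="0"><database name="d" version="1"><genes>
   <gene id="1" protId="s1|a|a.t1"/></genes></database></species>
 <species name="s2" NCBITaxId="0"><database name="d" version="1"><genes>
   <gene id="2" protId="s2|b|b.t1"/></genes></database></species>
 <groups>
  <orthologGroup id="1"><geneRef id="1"/><geneRef id="2"/></orthologGroup>
 </groups>
</orthoXML>
"""

NESTED_ORTHOXML = """<?xml version="1.0"?>
<orthoXML xmlns="http://orthoXML.org/2011/" version="0.3" origin="test" originVersion="1">
 <species name="s1" NCBITaxId="0"><database name="d" version="1"><genes>
   <gene id="1" protId="s1|a1|t"/><gene id="2" protId="s1|a2|t"/></genes></database></species>
 <species name="s2" NCBITaxId="0"><database name="d" version="1"><genes>
   <gene id="3" protId="s2|b1|t"/><gene id="4" protId="s2|b2|t"/></genes></database></species>
 <species name="s3" NCBITaxId="0"><database name="d" version="1"><genes>
   <gene id="5" protId="s3|c1|t"/><gene id="6" protId="s3|c2|t"/></genes></database></species>
 <groups>
  <orthologGroup id="1">
   <property name="TaxRange" value="root"/>
   <paralogGroup>
    <orthologGroup>
     <property name="TaxRange" value="consensus"/>
     <geneRef id="1"/><geneRef id="3"/><geneRef id="5"/>
    </orthologGroup>
    <orthologGroup>
     <property name="TaxRange" value="consensus"/>
     <geneRef id="2"/><geneRef id="4"/><geneRef id="6"/>
    </orthologGroup>
   </paralogGroup>
  </orthologGroup>
 </groups>
</orthoXML>
"""


class TestReadOrthoxml:
    def test_minimal_file(self):
        tree = SpeciesTree.from_newick("((s1,s2)consensus,outA)root;",
                                       ["s1", "s2"])
        forest = read_orthoxml(MINIMAL_ORTHOXML, tree)
        hogs = forest.ancestral_genome()
        assert len(hogs) == 1
        assert hogs[0].members == frozenset({("s1", "a"), ("s2", "b")})

    def test_nested_six_gene_file(self):
        tree = make_tree()
        forest = read_orthoxml(NESTED_ORTHOXML, tree)
        consensus = sorted(forest.ancestral_genome(),
                           key=lambda h: sorted(h.members))
        assert [h.members for h in consensus] == [
            frozenset({("s1", "a1"), ("s2", "b1"), ("s3", "c1")}),
            frozenset({("s1", "a2"), ("s2", "b2"), ("s3", "c2")})]
        root_hogs = forest.hogs_at(tree.root)
        assert len(root_hogs) == 1 and len(root_hogs[0].members) == 6
        for hog in consensus:
            assert hog.parent is root_hogs[0]

    def test_undeclared_generef_is_error(self):
        bad = MINIMAL_ORTHOXML.replace('<geneRef id="2"/>', '<geneRef id="999"/>')
        tree = SpeciesTree.from_newick("((s1,s2)consensus,outA)root;",
                                       ["s1", "s2"])
        with pytest.raises(DataError, match="999"):
            read_orthoxml(bad, tree)

    def test_unknown_species_is_error(self):
        bad = MINIMAL_ORTHOXML.replace('name="s2"', 'name="martian"')
        tree = SpeciesTree.from_newick("((s1,s2)consensus,outA)root;",
                                       ["s1", "s2"])
        with pytest.raises(DataError, match="martian"):
            read_orthoxml(bad, tree)
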