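"""Orthology over source pseudo-species and outgroup species.

Provides a deliberately simple engine — local alignment, strict
reciprocal best hits, and bottom-up connected-component grouping on the
species tree — plus ingestion of an externally computed orthoXML forest.
Both routes produce the same :class:`HogForest` structure.
"""
from __future__ import annotations

import functools
import itertools
import logging
import xml.etree.ElementTree as ET
from collections.abc import Iterable
from dataclasses import dataclass, field

from .errors import ConfigError, DataError
from .models import ProteinRecord, SpliceGroup, _slurp

log = logging.getLogger(__name__)


# ------------------------------------------------------------ species tree

class TreeNode:
    __slots__ = ("name", "children", "parent")

    def __init__(self, name: str | None = None):
        self.name = name
        self.children: list[TreeNode] = []
        self.parent: TreeNode | None = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaf_names(self) -> list[str]:
        if self.is_leaf:
            return [self.name]
        out: list[str] = []
        for child in self.children:
            out.extend(child.leaf_names())
        return out

    def __repr__(self):  # pragma: no cover
        return f"TreeNode({self.name!r})"


class SpeciesTree:
    """Rooted tree whose leaves are source names and outgroup species.

    One internal node — the *consensus node* — has exactly the source
    annotation names as leaf descendants; its ancestral gene repertoire
    is the candidate consensus.
    """

    def __init__(self, root: TreeNode, sources: Iterable[str]):
        self.root = root
        self.sources = sorted(sources)
        names = root.leaf_names()
        if len(names) != len(set(names)):
            raise ConfigError("species tree has duplicate leaf labels")
        self.leaves = {n: self._find_leaf(n) for n in names}
        missing = sorted(set(self.sources) - set(names))
        if missing:
            raise ConfigError(
                f"sources absent from species tree: {', '.join(missing)}")
        self.consensus_node = self._find_consensus_node()
        self.outgroups = sorted(set(names) - set(self.sources))

    @classmethod
    def from_newick(cls, source, sources: Iterable[str]) -> "SpeciesTree":
        import dendropy

        text = _slurp(source).strip()
        dtree = dendropy.Tree.get(data=text, schema="newick",
                                  preserve_underscores=True)
        root = cls._convert(dtree.seed_node)
        return cls(root, sources)

    @staticmethod
    def _convert(dnode) -> TreeNode:
        name = dnode.taxon.label if dnode.taxon is not None else dnode.label
        node = TreeNode(name)
        for child in dnode.child_nodes():
            cnode = SpeciesTree._convert(child)
            cnode.parent = node
            node.children.append(cnode)
        return node

    def _find_leaf(self, name: str) -> TreeNode:
        for node in self.postorder():
            if node.is_leaf and node.name == name:
                return node
        raise ConfigError(f"leaf {name!r} not found")

    def _find_consensus_node(self) -> TreeNode:
        want = set(self.sources)
        for node in self.postorder():
            if not node.is_leaf and set(node.leaf_names()) == want:
                return node
        if len(want) == 1:
            raise ConfigError("at least two sources are required")
        raise ConfigError(
            "no internal node has exactly the source annotations "
            f"({', '.join(sorted(want))}) as leaves")

    def postorder(self, node: TreeNode | None = None):
        node = node or self.root
        for child in node.children:
            yield from self.postorder(child)
        yield node

    def is_under(self, node: TreeNode, ancestor: TreeNode) -> bool:
        while node is not None:
            if node is ancestor:
                return True
            node = node.parent
        return False

    def lca(self, names: Iterable[str]) -> TreeNode:
        paths = []
        for name in names:
            node, path = self.leaves[name], []
            while node is not None:
                path.append(node)
                node = node.parent
            paths.append(path[::-1])
        lca = None
        for level in zip(*paths):
            if all(n is level[0] for n in level):
                lca = level[0]
            else:
                break
        return lca


# --------------------------------------------------------------- alignment

_GAP_OPEN = 11
_GAP_EXTEND = 1


@functools.lru_cache(maxsize=4)
def _aligner(gap_open: int = _GAP_OPEN, gap_extend: int = _GAP_EXTEND):
    from Bio.Align import PairwiseAligner, substitution_matrices

    matrix = substitution_matrices.load("BLOSUM62").copy()
    x = matrix.alphabet.index("X")
    for i in range(len(matrix.alphabet)):
        matrix[x, i] = matrix[i, x] = 0.0
    return PairwiseAligner(mode="local", substitution_matrix=matrix,
                           open_gap_score=-gap_open,
                           extend_gap_score=-gap_extend)


_STANDARD_AA = set("ARNDCQEGHILKMFPSTWYVBZX")


def _sanitize(seq: str) -> str:
    seq = seq.upper()
    if set(seq) <= _STANDARD_AA:
        return seq
    return "".join(c if c in _STANDARD_AA else "X" for c in seq)


def smith_waterman_score(a: str, b: str, gap_open: int = _GAP_OPEN,
                         gap_extend: int = _GAP_EXTEND) -> int:
    """Maximal local alignment score, BLOSUM62, affine gaps.

    A gap of length k costs ``gap_open + (k-1)*gap_extend``. X scores 0
    against everything. Empty input scores 0.
    """
    if not a or not b:
        return 0
    return int(_aligner(gap_open, gap_extend).score(_sanitize(a), _sanitize(b)))


def local_alignment(a: str, b: str) -> tuple[int, float]:
    """Score plus aligned fraction of the shorter sequence."""
    if not a or not b:
        return 0, 0.0
    aln = _aligner().align(_sanitize(a), _sanitize(b))[0]
    covered = sum(int(e) - int(s) for s, e in aln.aligned[0])
    return int(aln.score), covered / min(len(a), len(b))


@dataclass(frozen=True)
class AlignmentHit:
    query_id: str
    target_id: str
    score: int
    aligned_fraction: float


@dataclass
class EngineParams:
    min_score: int = 40
    min_cov: float = 0.5
    tolerance: int = 0
    # a raw score of 40 is background noise for longer proteins, so hits
    # must also reach this fraction of the smaller self-score (length-
    # adaptive, InParanoid-style); real orthologs at moderate divergence
    # score >= 0.6 of self, random pairs < 0.1
    min_self_ratio: float = 0.2
    kmer_size: int = 4
    # candidate prefilter: pairs must share this many k-mers before the
    # (expensive) alignment is attempted; short sequences need only one.
    min_shared_kmers: int = 2


@dataclass
class ProteinDatabase:
    """Per-species proteomes plus alternative-splicing groups."""

    proteomes: dict[str, list[ProteinRecord]]
    splice_groups: dict[str, list[SpliceGroup]] = field(default_factory=dict)

    def species(self) -> list[str]:
        return sorted(self.proteomes)

    def protein(self, pid: str) -> ProteinRecord:
        return self._index()[pid]

    @functools.lru_cache(maxsize=None)
    def _index(self) -> dict[str, ProteinRecord]:
        return {r.protein_id: r
                for recs in self.proteomes.values() for r in recs}

    __hash__ = object.__hash__


def select_main_isoform(proteins: list[ProteinRecord],
                        hits: list[AlignmentHit]) -> ProteinRecord:
    """Pick the isoform most similar to its detected homologues.

    Maximizes the summed hit score over the gene's isoforms; falls back
    to the longest protein, then the lexicographically smallest
    transcript id.
    """
    if not proteins:
        raise DataError("gene has no translatable isoforms")
    totals = {p.protein_id: 0 for p in proteins}
    for hit in hits:
        if hit.query_id in totals:
            totals[hit.query_id] += hit.score
    return min(proteins, key=lambda p: (-totals[p.protein_id],
                                        -len(p.sequence), p.transcript_id))


def _kmers(seq: str, k: int) -> frozenset:
    return frozenset(seq[i:i + k] for i in range(len(seq) - k + 1))


class _PairScorer:
    """Scores cross-species protein pairs with a shared k-mer prefilter."""

    def __init__(self, db: ProteinDatabase, params: EngineParams):
        self.db = db
        self.params = params
        self._kmer_cache = {r.protein_id: _kmers(_sanitize(r.sequence), params.kmer_size)
                            for recs in db.proteomes.values() for r in recs}
        self._score_cache: dict[tuple[str, str], tuple[int, float]] = {}
        self._self_cache: dict[str, int] = {}

    def _self_score(self, rec: ProteinRecord) -> int:
        score = self._self_cache.get(rec.protein_id)
        if score is None:
            score = smith_waterman_score(rec.sequence, rec.sequence)
            self._self_cache[rec.protein_id] = score
        return score

    def _candidate(self, a: ProteinRecord, b: ProteinRecord) -> bool:
        need = self.params.min_shared_kmers
        if min(len(a.sequence), len(b.sequence)) < 40:
            need = min(need, 1)
        if need <= 0:
            return True
        ka, kb = self._kmer_cache[a.protein_id], self._kmer_cache[b.protein_id]
        if len(ka) > len(kb):
            ka, kb = kb, ka
        shared = 0
        for kmer in ka:
            if kmer in kb:
                shared += 1
                if shared >= need:
                    return True
        return False

    def hit(self, a: ProteinRecord, b: ProteinRecord) -> AlignmentHit | None:
        """Alignment hit passing min_score and min_cov, else None."""
        key = (a.protein_id, b.protein_id) if a.protein_id < b.protein_id \
            else (b.protein_id, a.protein_id)
        cached = self._score_cache.get(key)
        if cached is None:
            if not self._candidate(a, b):
                cached = (0, 0.0)
            else:
                score = smith_waterman_score(a.sequence, b.sequence)
                if score < self.params.min_score:
                    cached = (score, 0.0)
                else:
                    cached = local_alignment(a.sequence, b.sequence)
            self._score_cache[key] = cached
        score, cov = cached
        if score < self.params.min_score or cov < self.params.min_cov:
            return None
        floor = self.params.min_self_ratio * min(self._self_score(a),
                                                 self._self_score(b))
        if score < floor:
            return None
        return AlignmentHit(a.protein_id, b.protein_id, score, cov)


def _main_isoforms(db: ProteinDatabase, scorer: _PairScorer) -> dict[str, ProteinRecord]:
    """One representative protein per (species, gene)."""
    chosen: dict[str, ProteinRecord] = {}
    for species in db.species():
        by_gene: dict[str, list[ProteinRecord]] = {}
        for rec in db.proteomes[species]:
            by_gene.setdefault(rec.gene_id, []).append(rec)
        others = [r for sp in db.species() if sp != species
                  for r in db.proteomes[sp]]
        for gid in sorted(by_gene):
            isoforms = sorted(by_gene[gid], key=lambda r: r.transcript_id)
            if len(isoforms) == 1:
                rec = isoforms[0]
            else:
                hits = [h for iso in isoforms for other in others
                        if (h := scorer.hit(iso, other)) is not None]
                rec = select_main_isoform(isoforms, hits)
            chosen[f"{species}|{gid}"] = rec
    return chosen


def infer_ortholog_pairs(db: ProteinDatabase,
                         params: EngineParams | None = None
                         ) -> set[tuple[str, str]]:
    """Strict reciprocal-best-hit ortholog pairs between all species pairs.

    Isoform selection happens first; RBH runs on one protein per gene.
    A pair is emitted iff each member scores within ``tolerance`` of the
    other's best cross-species score and passes min_score/min_cov.
    """
    params = params or EngineParams()
    if len(db.proteomes) < 2:
        raise ConfigError("orthology inference needs >= 2 species")
    scorer = _PairScorer(db, params)
    mains = _main_isoforms(db, scorer)
    per_species: dict[str, list[ProteinRecord]] = {}
    for key, rec in mains.items():
        per_species.setdefault(rec.source_name, []).append(rec)
    for recs in per_species.values():
        recs.sort(key=lambda r: r.protein_id)

    pairs: set[tuple[str, str]] = set()
    for sp_a, sp_b in itertools.combinations(sorted(per_species), 2):
        hits: dict[tuple[str, str], int] = {}
        best_a: dict[str, int] = {}
        best_b: dict[str, int] = {}
        for a in per_species[sp_a]:
            for b in per_species[sp_b]:
                hit = scorer.hit(a, b)
                if hit is None:
                    continue
                hits[(a.protein_id, b.protein_id)] = hit.score
                best_a[a.protein_id] = max(best_a.get(a.protein_id, 0), hit.score)
                best_b[b.protein_id] = max(best_b.get(b.protein_id, 0), hit.score)
        for (pa, pb), score in hits.items():
            if (score + params.tolerance >= best_a[pa]
                    and score + params.tolerance >= best_b[pb]):
                pairs.add((pa, pb) if pa < pb else (pb, pa))
    return pairs


# -------------------------------------------------------------------- HOGs

Member = tuple[str, str]  # (species, gene_id)


class Hog:
    __slots__ = ("hog_id", "node", "members", "children", "parent")

    def __init__(self, hog_id: str, node: TreeNode, members: frozenset,
                 children: list["Hog"]):
        self.hog_id = hog_id
        self.node = node
        self.members: frozenset[Member] = members
        self.children = children
        self.parent: Hog | None = None
        for child in children:
            child.parent = self

    def species(self) -> set[str]:
        return {sp for sp, _ in self.members}

    def ancestors(self):
        hog = self.parent
        while hog is not None:
            yield hog
            hog = hog.parent

    def __repr__(self):  # pragma: no cover
        return f"Hog({self.hog_id}, {sorted(self.members)})"


class HogForest:
    """Hierarchical groups attached to the nodes of a species tree."""

    def __init__(self, tree: SpeciesTree):
        self.tree = tree
        self.hogs_by_node: dict[int, list[Hog]] = {}

    def set_hogs(self, node: TreeNode, hogs: list[Hog]) -> None:
        self.hogs_by_node[id(node)] = hogs

    def hogs_at(self, node: TreeNode) -> list[Hog]:
        return self.hogs_by_node[id(node)]

    def ancestral_genome(self, node: TreeNode | None = None) -> list[Hog]:
        """HOG set at the consensus node (the candidate gene repertoire)."""
        return self.hogs_at(node or self.tree.consensus_node)


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[rj] = ri


def _build_forest(tree: SpeciesTree, leaf_genes: dict[str, list[Member]],
                  merge_groups_at) -> HogForest:
    """Generic bottom-up HOG construction.

    ``merge_groups_at(node)`` yields member sets that must end up in one
    HOG at that node; connected components of child HOGs under those
    constraints become the node's HOGs.
    """
    forest = HogForest(tree)
    for node in tree.postorder():
        if node.is_leaf:
            hogs = [Hog(f"{node.name}:{i}", node, frozenset({m}), [])
                    for i, m in enumerate(sorted(leaf_genes.get(node.name, [])))]
            forest.set_hogs(node, hogs)
            continue
        child_hogs = [h for c in node.children for h in forest.hogs_at(c)]
        idx_of: dict[Member, int] = {}
        for i, hog in enumerate(child_hogs):
            for m in hog.members:
                idx_of[m] = i
        uf = _UnionFind(len(child_hogs))
        for group in merge_groups_at(node):
            ids = sorted({idx_of[m] for m in group if m in idx_of})
            for j in ids[1:]:
                uf.union(ids[0], j)
        components: dict[int, list[Hog]] = {}
        for i, hog in enumerate(child_hogs):
            components.setdefault(uf.find(i), []).append(hog)
        comps = sorted(components.values(),
                       key=lambda hogs: min(min(h.members) for h in hogs))
        label = node.name or "node"
        hogs = [Hog(f"{label}:{i}", node,
                    frozenset().union(*(h.members for h in hogs_in)), hogs_in)
                for i, hogs_in in enumerate(comps)]
        forest.set_hogs(node, hogs)
    return forest


def build_hogs(pairs: Iterable[tuple[str, str]], tree: SpeciesTree,
               db: ProteinDatabase) -> HogForest:
    """Connected-component HOGs from ortholog pairs, bottom-up on the tree.

    Each pair is applied at the LCA of its two species, so merging
    happens exactly where the orthology evidence crosses child subtrees.
    """
    leaf_genes: dict[str, list[Member]] = {}
    for species, recs in db.proteomes.items():
        genes = sorted({r.gene_id for r in recs})
        leaf_genes[species] = [(species, g) for g in genes]

    index = db._index()
    pairs_at_node: dict[int, list[tuple[Member, Member]]] = {}
    for pa, pb in sorted(pairs):
        try:
            ra, rb = index[pa], index[pb]
        except KeyError as exc:
            raise DataError(f"pair references unknown protein {exc}") from None
        for rec in (ra, rb):
            if rec.source_name not in tree.leaves:
                raise DataError(
                    f"species {rec.source_name!r} is not a tree leaf")
        node = tree.lca([ra.source_name, rb.source_name])
        pairs_at_node.setdefault(id(node), []).append(
            ((ra.source_name, ra.gene_id), (rb.source_name, rb.gene_id)))

    def merge_groups_at(node):
        for a, b in pairs_at_node.get(id(node), []):
            yield (a, b)

    return _build_forest(tree, leaf_genes, merge_groups_at)


# ---------------------------------------------------------------- orthoXML

def _local(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def read_orthoxml(source, tree: SpeciesTree) -> HogForest:
    """Ingest a HOG forest from orthoXML.

    Nested orthologGroup elements become parent/child HOGs; paralogGroup
    elements are transparent. A group's taxonomic level comes from its
    ``TaxRange`` property when present, else from the LCA of its member
    species.
    """
    text = _slurp(source)
    root = ET.fromstring(text)

    gene_of: dict[str, Member] = {}
    bad_species = []
    for sp_el in root.iter():
        if _local(sp_el.tag) != "species":
            continue
        sp_name = sp_el.get("name")
        if sp_name not in tree.leaves:
            bad_species.append(sp_name)
            continue
        for gene_el in sp_el.iter():
            if _local(gene_el.tag) != "gene":
                continue
            gid = gene_el.get("geneId") or gene_el.get("protId")
            prot = gene_el.get("protId") or gid
            if prot and "|" in prot:
                parts = prot.split("|")
                if len(parts) == 3:
                    gid = parts[1]
            gene_of[gene_el.get("id")] = (sp_name, gid)
    if bad_species:
        raise DataError("orthoXML species absent from tree: "
                        + ", ".join(sorted(bad_species)))

    node_by_name = {}
    for node in tree.postorder():
        if node.name:
            node_by_name[node.name] = node

    raw_groups: list[tuple[TreeNode, frozenset]] = []

    def walk(el) -> frozenset:
        members: set[Member] = set()
        level = None
        for child in el:
            tag = _local(child.tag)
            if tag == "geneRef":
                ref = child.get("id")
                if ref not in gene_of:
                    raise DataError(f"orthoXML geneRef id={ref} not declared")
                members.add(gene_of[ref])
            elif tag in ("orthologGroup", "paralogGroup"):
                members |= walk(child)
            elif tag == "property" and child.get("name") in ("TaxRange", "level"):
                level = child.get("value")
        if _local(el.tag) == "orthologGroup":
            if level is not None and level in node_by_name:
                node = node_by_name[level]
            else:
                node = tree.lca(sorted({sp for sp, _ in members}))
            raw_groups.append((node, frozenset(members)))
        return frozenset(members)

    for el in root.iter():
        if _local(el.tag) == "groups":
            for group_el in el:
                if _local(group_el.tag) in ("orthologGroup", "paralogGroup"):
                    walk(group_el)

    leaf_genes: dict[str, list[Member]] = {}
    for member in sorted(set(gene_of.values())):
        leaf_genes.setdefault(member[0], []).append(member)

    groups_at_node: dict[int, list[frozenset]] = {}
    for node, members in raw_groups:
        groups_at_node.setdefault(id(node), []).append(members)

    def merge_groups_at(node):
        yield from groups_at_node.get(id(node), [])

    return _build_forest(tree, leaf_genes, merge_groups_at)
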