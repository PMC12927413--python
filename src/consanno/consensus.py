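"""Consensus extraction from the ancestral gene repertoire.

A candidate gene (one HOG at the consensus node) is retained when at
least two sources predicted it, or when a single-source prediction has a
detected ortholog in any outgroup species. The retained HOG contributes
one representative gene model — longest CDS by default, or the highest
ranking source under ``--priority`` — together with all its isoforms.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .errors import ConfigError, DataError
from .models import AnnotationSet, GeneModel
from .orthology import HogForest, SpeciesTree

log = logging.getLogger(__name__)


@dataclass
class SupportRecord:
    """Binary support vector of one candidate consensus gene."""

    hog_id: str
    source_bits: dict[str, int]
    outgroup_bits: dict[str, int]
    members_by_source: dict[str, list[str]]

    @property
    def n_sources(self) -> int:
        return sum(self.source_bits.values())

    @property
    def n_outgroups(self) -> int:
        return sum(self.outgroup_bits.values())

    def label(self) -> str:
        parts = [s for s, bit in self.source_bits.items() if bit]
        if self.n_outgroups:
            parts.append("outgroups")
        return "+".join(parts)


@dataclass
class ConsensusGene:
    hog_id: str
    representative: GeneModel
    representative_source: str
    support: SupportRecord


@dataclass
class ConsensusAnnotation:
    genes: list[ConsensusGene]
    sources: list[str]
    outgroups: list[str]
    options: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.genes)

    def as_annotation_set(self, name: str = "consensus") -> AnnotationSet:
        """Flatten to an AnnotationSet (gene ids namespaced by source)."""
        from .models import TranscriptModel

        ann = AnnotationSet(source_name=name)
        for cg in self.genes:
            gene = cg.representative
            gid = f"{cg.representative_source}.{gene.gene_id}"
            transcripts = [
                TranscriptModel(f"{gid}.{t.transcript_id}", gid, list(t.segments))
                for t in gene.transcripts]
            ann.add(GeneModel(gid, name, transcripts))
        return ann


def compute_support(forest: HogForest, tree: SpeciesTree,
                    outgroup_evidence: str = "hog",
                    pairs=None) -> list[SupportRecord]:
    """One SupportRecord per HOG at the consensus node.

    Outgroup evidence: ``hog`` (default) sets the bit for species s when
    a gene of s shares an ancestral HOG above the consensus node with
    this HOG's members; ``pairs`` requires a direct ortholog pair.
    """
    if outgroup_evidence not in ("hog", "pairs"):
        raise ConfigError(f"unknown outgroup_evidence {outgroup_evidence!r}")
    if outgroup_evidence == "pairs" and pairs is None:
        raise ConfigError("outgroup_evidence='pairs' needs the pair set")

    try:
        hogs = forest.ancestral_genome()
    except KeyError:
        raise DataError("HOG forest lacks the consensus node level") from None

    pair_partners: dict[tuple[str, str], set[str]] = {}
    if outgroup_evidence == "pairs":
        # pairs are namespaced protein-id tuples "<species>|<gene>|<transcript>"
        for pa, pb in pairs:
            ma, mb = _member_of(pa), _member_of(pb)
            pair_partners.setdefault(ma, set()).add(mb[0])
            pair_partners.setdefault(mb, set()).add(ma[0])

    records = []
    for hog in hogs:
        source_bits = {s: 0 for s in tree.sources}
        members: dict[str, list[str]] = {}
        for species, gene_id in sorted(hog.members):
            if species not in source_bits:
                raise DataError(
                    f"HOG {hog.hog_id} at consensus node contains non-source "
                    f"species {species!r}")
            source_bits[species] = 1
            members.setdefault(species, []).append(gene_id)
        outgroup_bits = {s: 0 for s in tree.outgroups}
        if outgroup_evidence == "hog":
            for ancestor in hog.ancestors():
                for species, _gid in ancestor.members:
                    if species in outgroup_bits:
                        outgroup_bits[species] = 1
        else:
            for member in hog.members:
                for species in pair_partners.get(member, ()):
                    if species in outgroup_bits:
                        outgroup_bits[species] = 1
        records.append(SupportRecord(hog.hog_id, source_bits, outgroup_bits,
                                     members))
    return records


def _member_of(pid: str) -> tuple[str, str]:
    parts = pid.split("|")
    if len(parts) != 3:
        raise DataError(f"protein id {pid!r} is not namespaced")
    return parts[0], parts[1]


def retain_genes(records: list[SupportRecord]) -> list[SupportRecord]:
    """Retention rule: >=2 sources, or >=1 source plus any outgroup."""
    return [r for r in records
            if r.n_sources >= 2 or (r.n_sources >= 1 and r.n_outgroups >= 1)]


def select_representative(record: SupportRecord,
                          annotations: dict[str, AnnotationSet],
                          priority: list[str] | None = None,
                          source_order: list[str] | None = None
                          ) -> tuple[GeneModel, str]:
    """Pick the representative gene model of a retained HOG.

    Default: the member with the longest isoform CDS (nt). Priority
    mode: the member from the highest-ranking listed source present in
    the HOG (longest CDS within that source); falls back to the default
    when no listed source is present. Ties break on declared source
    order, then smallest gene id.
    """
    source_order = source_order or sorted(annotations)
    order_index = {s: i for i, s in enumerate(source_order)}

    candidates: list[tuple[str, GeneModel]] = []
    for source, gene_ids in record.members_by_source.items():
        ann = annotations.get(source)
        if ann is None:
            raise DataError(f"no annotation loaded for source {source!r}")
        for gid in gene_ids:
            gene = ann.genes.get(gid)
            if gene is None:
                raise DataError(f"member gene {gid!r} missing from {source!r}")
            candidates.append((source, gene))
    if not candidates:
        raise DataError(f"HOG {record.hog_id} has no resolvable members")

    if priority:
        unknown = sorted(set(priority) - set(annotations))
        if unknown:
            raise ConfigError(
                f"priority lists unknown sources: {', '.join(unknown)}")
        ranks = {s: i for i, s in enumerate(priority)}
        ranked = [c for c in candidates if c[0] in ranks]
        if ranked:
            best_rank = min(ranks[s] for s, _ in ranked)
            pool = [c for c in ranked if ranks[c[0]] == best_rank]
            source, gene = min(
                pool, key=lambda c: (-c[1].longest_cds, c[1].gene_id))
            return gene, source

    source, gene = min(candidates, key=lambda c: (
        -c[1].longest_cds, order_index.get(c[0], len(order_index)),
        c[1].gene_id))
    return gene, source


def assemble_consensus(retained: list[SupportRecord],
                       representatives: list[tuple[GeneModel, str]],
                       annotations: dict[str, AnnotationSet],
                       tree: SpeciesTree,
                       options: dict | None = None) -> ConsensusAnnotation:
    genes = [ConsensusGene(rec.hog_id, gene, source, rec)
             for rec, (gene, source) in zip(retained, representatives)]
    genes.sort(key=lambda cg: (cg.representative.contig,
                               cg.representative.start,
                               cg.representative_source,
                               cg.representative.gene_id))
    return ConsensusAnnotation(genes, sources=list(tree.sources),
                               outgroups=list(tree.outgroups),
                               options=dict(options or {}))


def write_reports(consensus: ConsensusAnnotation, out_prefix: str
                  ) -> tuple[str, str]:
    """Write ``<prefix>_report.txt`` and ``<prefix>_detailed_report.txt``.

    Returns the two paths.
    """
    combos: dict[str, int] = {}
    rep_usage: dict[str, int] = {s: 0 for s in consensus.sources}
    for cg in consensus.genes:
        combos[cg.support.label()] = combos.get(cg.support.label(), 0) + 1
        rep_usage[cg.representative_source] += 1

    summary_path = f"{out_prefix}_report.txt"
    with open(summary_path, "w") as fh:
        fh.write("# consensus annotation report\n")
        fh.write(f"total_retained\t{len(consensus.genes)}\n")
        fh.write("\n# genes per support combination\n")
        for label in sorted(combos):
            fh.write(f"{label}\t{combos[label]}\n")
        fh.write("\n# representative gene models per source\n")
        for source in consensus.sources:
            fh.write(f"{source}\t{rep_usage[source]}\n")

    detailed_path = f"{out_prefix}_detailed_report.txt"
    with open(detailed_path, "w") as fh:
        header = (["hog_id", "gene_id", "source"] + consensus.sources
                  + consensus.outgroups + ["members"])
        fh.write("\t".join(header) + "\n")
        for cg in consensus.genes:
            members = ";".join(
                f"{s}:{g}" for s in consensus.sources
                for g in cg.support.members_by_source.get(s, []))
            row = ([cg.hog_id, cg.representative.gene_id,
                    cg.representative_source]
                   + [str(cg.support.source_bits[s]) for s in consensus.sources]
                   + [str(cg.support.outgroup_bits[s]) for s in consensus.outgroups]
                   + [members])
            fh.write("\t".join(row) + "\n")
    return summary_path, detailed_path
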