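"""Synthetic genomes, truth annotations, corrupted sources, outgroups.

Everything is generated with a seeded RNG so ground truth is known
exactly: which genes each source kept, dropped or invented, and which
outgroup protein descends from which truth gene. Decoy ORFs (the pool
of "false" gene predictions) are planted in intergenic space at
simulation time and handed out to sources without replacement, so no
false gene is ever shared between two sources.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .annotation_io import extract_proteome, translate_cds
from .errors import ConfigError, DataError
from .models import (
    AnnotationSet,
    CdsSegment,
    GeneModel,
    GenomeSequence,
    ProteinRecord,
    TranscriptModel,
    protein_id,
    reverse_complement,
)

_AA = "ACDEFGHIKLMNPQRSTVWY"
_STOPS = ("TAA", "TAG", "TGA")


def _codon_table() -> dict[str, list[str]]:
    from Bio.Data.CodonTable import standard_dna_table

    table: dict[str, list[str]] = {}
    for codon, aa in sorted(standard_dna_table.forward_table.items()):
        table.setdefault(aa, []).append(codon)
    return table


_BACK = _codon_table()


@dataclass
class SimulationConfig:
    n_genes: int = 50
    contig_length: int | None = None  # autosized when None
    isoform_rate: float = 0.2
    drop_rate: float = 0.0
    false_rate: float = 0.0
    boundary_jitter_nt: int = 0
    outgroup_divergence: float = 0.1
    seed: int = 0
    n_decoys: int | None = None
    min_protein_len: int = 60
    max_protein_len: int = 180
    # decoys are rejection-sampled until their best local-alignment score
    # against truth proteins and earlier decoys stays below this (kept
    # under the engine's default min_score so false genes can never form
    # an ortholog pair)
    decoy_max_score: int = 38

    def __post_init__(self):
        for name in ("isoform_rate", "drop_rate", "false_rate",
                     "outgroup_divergence"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ConfigError(f"{name} must be in [0,1], got {value}")
        if self.n_genes < 1:
            raise ConfigError("n_genes must be positive")


@dataclass
class TruthSet:
    genome: GenomeSequence
    truth: AnnotationSet
    decoys: list[GeneModel]
    config: SimulationConfig
    contig: str = "chr1"
    sources: dict[str, AnnotationSet] = field(default_factory=dict)
    source_labels: dict[str, dict[str, str]] = field(default_factory=dict)
    dropped: dict[str, list[str]] = field(default_factory=dict)
    outgroups: dict[str, list[ProteinRecord]] = field(default_factory=dict)
    ortholog_maps: dict[str, dict[str, str]] = field(default_factory=dict)
    _decoy_cursor: int = 0

    def truth_proteins(self) -> list[ProteinRecord]:
        return extract_proteome(self.truth, self.genome).records

    def default_tree(self) -> str:
        inner = ",".join(sorted(self.sources))
        outs = sorted(self.outgroups)
        if not outs:
            raise ConfigError("no outgroups derived yet")
        outer = outs[0] if len(outs) == 1 else "(" + ",".join(outs) + ")"
        return f"(({inner})consensus,{outer})root;"


def _random_protein(rng, length: int) -> str:
    body = "".join(_AA[i] for i in rng.integers(0, len(_AA), size=length - 1))
    return "M" + body


def _back_translate(rng, protein: str) -> str:
    codons = []
    for aa in protein:
        options = _BACK[aa]
        codons.append(options[rng.integers(0, len(options))])
    codons.append(_STOPS[rng.integers(0, len(_STOPS))])
    return "".join(codons)


def _random_nt(rng, length: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))


def _split_codons(rng, cds: str, n_seg: int) -> list[str]:
    """Split a CDS into n_seg chunks at codon boundaries (each >= 2 codons)."""
    n_codons = len(cds) // 3
    if n_seg == 1 or n_codons < 2 * n_seg:
        return [cds]
    cuts = sorted(rng.choice(np.arange(2, n_codons - 2), size=n_seg - 1,
                             replace=False))
    while len(cuts) > 1 and min(b - a for a, b in zip(cuts, cuts[1:])) < 2:
        cuts = sorted(rng.choice(np.arange(2, n_codons - 2), size=n_seg - 1,
                                 replace=False))
    chunks, prev = [], 0
    for cut in cuts:
        chunks.append(cds[prev * 3:cut * 3])
        prev = cut
    chunks.append(cds[prev * 3:])
    return chunks


def _build_gene(rng, gene_id: str, contig: str, offset: int, strand: str,
                chunks: list[str], with_isoform: bool
                ) -> tuple[str, GeneModel]:
    """Lay out exon chunks and introns; return (genomic block, gene model)."""
    introns = [_random_nt(rng, int(rng.integers(20, 101)))
               for _ in range(len(chunks) - 1)]
    parts, coords, pos = [], [], 0
    for i, chunk in enumerate(chunks):
        parts.append(chunk)
        coords.append((pos, pos + len(chunk)))
        pos += len(chunk)
        if i < len(introns):
            parts.append(introns[i])
            pos += len(introns[i])
    block = "".join(parts)
    if strand == "-":
        block = reverse_complement(block)
        coords = [(len(block) - e, len(block) - s) for s, e in coords][::-1]
        # coords back in genomic order; transcription order is reversed

    def segments(keep: list[int]) -> list[CdsSegment]:
        # `keep` indexes chunks in transcription order; chunks are codon
        # multiples, so every segment keeps phase 0 in every isoform
        genomic = keep if strand == "+" else [len(chunks) - 1 - k
                                              for k in reversed(keep)]
        return [CdsSegment(contig, offset + coords[gi][0],
                           offset + coords[gi][1], strand, 0)
                for gi in sorted(genomic)]

    transcripts = [TranscriptModel(f"{gene_id}.t1", gene_id,
                                   segments(list(range(len(chunks)))))]
    if with_isoform and len(chunks) >= 3:
        keep = [i for i in range(len(chunks)) if i != 1]
        transcripts.append(TranscriptModel(f"{gene_id}.t2", gene_id,
                                           segments(keep)))
    return block, GeneModel(gene_id, "truth", transcripts)


def _sample_decoy_proteins(rng, n_decoys: int, truth_proteins: list[str],
                           max_score: int) -> list[str]:
    """Random proteins provably unrelated to truth (and to each other).

    Candidates whose best local-alignment score against any truth
    protein or earlier decoy reaches ``max_score`` are regenerated;
    diverged outgroup copies of truth proteins can only score lower, so
    accepted decoys can never seed an ortholog pair under the engine's
    default thresholds.
    """
    from .orthology import smith_waterman_score

    decoys: list[str] = []
    for _ in range(n_decoys):
        best_candidate, best_seen = None, None
        for _attempt in range(500):
            candidate = _random_protein(rng, int(rng.integers(40, 81)))
            top = 0
            for other in truth_proteins + decoys:
                top = max(top, smith_waterman_score(candidate, other))
                if top >= max_score:
                    break
            if top < max_score:
                best_candidate = candidate
                break
            if best_seen is None or top < best_seen:
                best_candidate, best_seen = candidate, top
        decoys.append(best_candidate)
    return decoys


def simulate_truth(config: SimulationConfig) -> TruthSet:
    """Generate a genome with non-overlapping genes and a decoy ORF pool."""
    rng = np.random.default_rng(config.seed)
    n = config.n_genes
    n_decoys = config.n_decoys
    if n_decoys is None:
        n_decoys = 4 * math.ceil(config.false_rate * n)

    iso_count = int(config.isoform_rate * n)
    iso_flags = np.zeros(n, dtype=bool)
    if iso_count:
        iso_flags[rng.choice(n, size=iso_count, replace=False)] = True

    truth_proteins = [
        _random_protein(rng, int(rng.integers(config.min_protein_len,
                                              config.max_protein_len + 1)))
        for _ in range(n)]
    decoy_proteins = _sample_decoy_proteins(rng, n_decoys, truth_proteins,
                                            config.decoy_max_score)

    contig = "chr1"
    pieces: list[str] = []
    pos = 0
    truth = AnnotationSet(source_name="truth")
    decoys: list[GeneModel] = []

    def spacer():
        nonlocal pos
        gap = _random_nt(rng, int(rng.integers(100, 301)))
        pieces.append(gap)
        pos += len(gap)

    decoy_slots = sorted(rng.choice(n, size=n_decoys, replace=True).tolist()) \
        if n_decoys else []
    decoy_idx = 0

    for i in range(n):
        spacer()
        while decoy_idx < len(decoy_slots) and decoy_slots[decoy_idx] == i:
            cds = _back_translate(rng, decoy_proteins[decoy_idx])
            strand = "+-"[rng.integers(0, 2)]
            block, gene = _build_gene(rng, f"d{decoy_idx + 1:04d}", contig,
                                      pos, strand, [cds], False)
            pieces.append(block)
            pos += len(block)
            decoys.append(gene)
            decoy_idx += 1
            spacer()
        cds = _back_translate(rng, truth_proteins[i])
        n_seg = 3 if iso_flags[i] else int(rng.integers(1, 3))
        chunks = _split_codons(rng, cds, n_seg)
        strand = "+-"[rng.integers(0, 2)]
        block, gene = _build_gene(rng, f"g{i + 1:04d}", contig, pos, strand,
                                  chunks, bool(iso_flags[i]))
        pieces.append(block)
        pos += len(block)
        truth.add(gene)
    spacer()

    sequence = "".join(pieces)
    if config.contig_length is not None:
        if len(sequence) > config.contig_length:
            raise DataError(
                f"contig_length {config.contig_length} too short for "
                f"{n} genes (need {len(sequence)})")
        sequence += _random_nt(rng, config.contig_length - len(sequence))

    return TruthSet(GenomeSequence({contig: sequence}), truth, decoys, config)


def _jitter_gene(rng, gene: GeneModel, jitter: int) -> GeneModel:
    """Trim terminal segment boundaries by multiples of 3 (frame-safe)."""
    max_steps = jitter // 3
    d5 = 3 * int(rng.integers(0, max_steps + 1))
    d3 = 3 * int(rng.integers(0, max_steps + 1))
    transcripts = []
    for tx in gene.transcripts:
        segs = list(tx.segments)
        first, last = segs[0], segs[-1]
        if gene.strand == "+":
            t5 = min(d5, first.length - 9)
            t3 = min(d3, last.length - 9)
            segs[0] = CdsSegment(first.contig, first.start + max(t5, 0),
                                 first.end, first.strand, first.phase)
            last = segs[-1]
            segs[-1] = CdsSegment(last.contig, last.start,
                                  last.end - max(t3, 0), last.strand,
                                  last.phase)
        else:
            t5 = min(d5, last.length - 9)
            t3 = min(d3, first.length - 9)
            segs[-1] = CdsSegment(last.contig, last.start,
                                  last.end - max(t5, 0), last.strand,
                                  last.phase)
            first = segs[0]
            segs[0] = CdsSegment(first.contig, first.start + max(t3, 0),
                                 first.end, first.strand, first.phase)
        transcripts.append(TranscriptModel(tx.transcript_id, gene.gene_id,
                                           segs))
    return GeneModel(gene.gene_id, gene.source_name, transcripts)


def derive_source_annotation(truth_set: TruthSet, name: str,
                             drop_rate: float = 0.0, false_rate: float = 0.0,
                             boundary_jitter_nt: int = 0,
                             seed: int = 0) -> AnnotationSet:
    """Corrupt the truth into one source annotation with known labels."""
    for rate in (drop_rate, false_rate):
        if not 0.0 <= rate <= 1.0:
            raise ConfigError(f"rate {rate} outside [0,1]")
    rng = np.random.default_rng(seed)
    gene_ids = sorted(truth_set.truth.genes)
    n = len(gene_ids)
    n_drop = int(drop_rate * n)
    dropped = sorted(rng.choice(gene_ids, size=n_drop, replace=False).tolist()) \
        if n_drop else []
    dropped_set = set(dropped)

    n_false = int(false_rate * n)
    if truth_set._decoy_cursor + n_false > len(truth_set.decoys):
        raise DataError(
            f"decoy pool exhausted ({len(truth_set.decoys)} decoys); "
            "raise n_decoys in SimulationConfig")
    false_genes = truth_set.decoys[
        truth_set._decoy_cursor:truth_set._decoy_cursor + n_false]
    truth_set._decoy_cursor += n_false

    ann = AnnotationSet(source_name=name)
    labels: dict[str, str] = {}
    for gid in gene_ids:
        if gid in dropped_set:
            continue
        gene = truth_set.truth.genes[gid]
        if boundary_jitter_nt > 0:
            gene = _jitter_gene(rng, gene, boundary_jitter_nt)
        ann.add(GeneModel(gid, name, [
            TranscriptModel(t.transcript_id, gid, list(t.segments))
            for t in gene.transcripts]))
        labels[gid] = "true_kept"
    for decoy in false_genes:
        ann.add(GeneModel(decoy.gene_id, name, [
            TranscriptModel(t.transcript_id, decoy.gene_id, list(t.segments))
            for t in decoy.transcripts]))
        labels[decoy.gene_id] = "false"

    truth_set.sources[name] = ann
    truth_set.source_labels[name] = labels
    truth_set.dropped[name] = dropped
    return ann


def derive_outgroup_proteome(truth_set: TruthSet, name: str,
                             divergence: float = 0.1, seed: int = 0
                             ) -> tuple[list[ProteinRecord], dict[str, str]]:
    """Diverged copy of each truth protein (first isoform), plus the map."""
    if not 0.0 <= divergence <= 1.0:
        raise ConfigError(f"divergence {divergence} outside [0,1]")
    rng = np.random.default_rng(seed)
    records: list[ProteinRecord] = []
    mapping: dict[str, str] = {}
    for gid in sorted(truth_set.truth.genes):
        gene = truth_set.truth.genes[gid]
        aa = translate_cds(gene.transcripts[0].segments, truth_set.genome)
        if divergence > 0:
            chars = list(aa)
            hits = np.nonzero(rng.random(len(chars)) < divergence)[0]
            for i in hits:
                alternatives = _AA.replace(chars[i], "")
                chars[i] = alternatives[rng.integers(0, len(alternatives))]
            aa = "".join(chars)
        pid = protein_id(name, gid, f"{gid}.t1")
        records.append(ProteinRecord(pid, aa, name, gid, f"{gid}.t1"))
        mapping[gid] = pid
    truth_set.outgroups[name] = records
    truth_set.ortholog_maps[name] = mapping
    return records, mapping


# ------------------------------------------------------------ demo fixture

@dataclass
class DemoFixture:
    genome: GenomeSequence
    annotations: dict[str, AnnotationSet]
    outgroups: dict[str, list[ProteinRecord]]
    tree_newick: str
    expected_retained: set[str]
    truth: AnnotationSet


def six_gene_fixture(seed: int = 42) -> DemoFixture:
    """Three sources over six genes, one outgroup.

    Genes g0001–g0004 are each predicted by two sources; g0005 by one
    source but with an outgroup ortholog; g0006 by one source with no
    outgroup evidence. A correct consensus is exactly g0001–g0005.
    """
    ts = simulate_truth(SimulationConfig(n_genes=6, isoform_rate=0.34,
                                         seed=seed))
    membership = {
        "src1": ["g0001", "g0002", "g0005"],
        "src2": ["g0001", "g0003", "g0004", "g0006"],
        "src3": ["g0002", "g0003", "g0004"],
    }
    annotations: dict[str, AnnotationSet] = {}
    for source, gids in membership.items():
        ann = AnnotationSet(source_name=source)
        for gid in gids:
            gene = ts.truth.genes[gid]
            ann.add(GeneModel(gid, source, [
                TranscriptModel(t.transcript_id, gid, list(t.segments))
                for t in gene.transcripts]))
        annotations[source] = ann
        ts.sources[source] = ann

    with_ortholog = {"g0001", "g0002", "g0003", "g0005"}
    records, mapping = derive_outgroup_proteome(ts, "outA", divergence=0.05,
                                                seed=seed + 1)
    records = [r for r in records if r.gene_id in with_ortholog]
    ts.outgroups["outA"] = records
    ts.ortholog_maps["outA"] = {g: p for g, p in mapping.items()
                                if g in with_ortholog}

    return DemoFixture(
        genome=ts.genome,
        annotations=annotations,
        outgroups={"outA": records},
        tree_newick="((src1,src2,src3)consensus,outA)root;",
        expected_retained={"g0001", "g0002", "g0003", "g0004", "g0005"},
        truth=ts.truth,
    )
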