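"""Sensitivity/precision of a query annotation against a reference.

Matching rules follow GffCompare semantics: exact exon boundaries at the
exon level; identical intron chains with a 100-nt tolerance on the outer
ends of terminal exons at the transcript level (single-exon transcripts
match at >= 80% overlap of the reference exon); locus level clusters
overlapping same-strand reference genes and asks for at least one
transcript-level match per locus. CDS segments stand in for exons —
the whole pipeline is CDS-only.
"""
from __future__ import annotations

from dataclasses import dataclass

from .errors import DataError
from .models import AnnotationSet, TranscriptModel

TERMINAL_TOLERANCE_NT = 100
SINGLE_EXON_MIN_OVERLAP = 0.8

LEVELS = ("exon", "locus", "transcript")


@dataclass
class LevelStats:
    level: str
    tp: int
    fn: int
    fp: int

    @property
    def sensitivity(self) -> float:
        return 100.0 * self.tp / (self.tp + self.fn) if self.tp + self.fn else 0.0

    @property
    def precision(self) -> float:
        return 100.0 * self.tp / (self.tp + self.fp) if self.tp + self.fp else 0.0

    def as_row(self) -> tuple:
        return (self.level, self.tp, self.fn, self.fp,
                round(self.sensitivity, 2), round(self.precision, 2))


def transcript_match(query: TranscriptModel, ref: TranscriptModel,
                     terminal_tolerance: int = TERMINAL_TOLERANCE_NT,
                     single_exon_min_overlap: float = SINGLE_EXON_MIN_OVERLAP
                     ) -> bool:
    if query.contig != ref.contig or query.strand != ref.strand:
        return False
    q_multi, r_multi = len(query.segments) > 1, len(ref.segments) > 1
    if q_multi != r_multi:
        return False
    if q_multi:
        if query.introns() != ref.introns():
            return False
        return (abs(query.start - ref.start) <= terminal_tolerance
                and abs(query.end - ref.end) <= terminal_tolerance)
    overlap = min(query.end, ref.end) - max(query.start, ref.start)
    return overlap >= single_exon_min_overlap * (ref.end - ref.start)


def _dedup(transcripts) -> list[TranscriptModel]:
    seen, out = set(), []
    for tx in transcripts:
        key = tx.chain_key()
        if key not in seen:
            seen.add(key)
            out.append(tx)
    return out


def _exon_set(transcripts) -> set[tuple]:
    return {(s.contig, s.strand, s.start, s.end)
            for tx in transcripts for s in tx.segments}


def _cluster_loci(annotation: AnnotationSet) -> list[list[TranscriptModel]]:
    """Single-linkage clusters of overlapping same-strand gene spans."""
    genes = sorted(annotation.genes.values(),
                   key=lambda g: (g.contig, g.strand, g.start, g.end))
    loci: list[list] = []
    current: list = []
    current_end = -1
    current_key = None
    for gene in genes:
        key = (gene.contig, gene.strand)
        if current and key == current_key and gene.start < current_end:
            current.append(gene)
            current_end = max(current_end, gene.end)
        else:
            if current:
                loci.append(current)
            current, current_key, current_end = [gene], key, gene.end
    if current:
        loci.append(current)
    return [[tx for gene in locus for tx in gene.transcripts]
            for locus in loci]


def evaluate_annotation(query: AnnotationSet,
                        ref: AnnotationSet) -> list[LevelStats]:
    """Exon-, locus- and transcript-level stats of query vs reference.

    Duplicate query transcripts (identical segment chains) are discarded
    first.
    """
    if not ref.genes:
        raise DataError("empty reference annotation: sensitivity undefined")

    q_txs = _dedup(query.transcripts())
    r_txs = list(ref.transcripts())

    # exon level: exact boundary matches of distinct intervals
    q_exons, r_exons = _exon_set(q_txs), _exon_set(r_txs)
    exon = LevelStats("exon", tp=len(q_exons & r_exons),
                      fn=len(r_exons - q_exons), fp=len(q_exons - r_exons))

    # transcript level (index queries by contig/strand to stay subquadratic)
    q_by_key: dict[tuple, list[TranscriptModel]] = {}
    for tx in q_txs:
        q_by_key.setdefault((tx.contig, tx.strand), []).append(tx)

    matched_q: set[int] = set()
    matched_r: set[int] = set()
    ref_match_of: dict[int, bool] = {}
    for ri, rtx in enumerate(r_txs):
        for qtx in q_by_key.get((rtx.contig, rtx.strand), []):
            if qtx.end <= rtx.start - TERMINAL_TOLERANCE_NT:
                continue
            if qtx.start >= rtx.end + TERMINAL_TOLERANCE_NT:
                continue
            if transcript_match(qtx, rtx):
                matched_r.add(ri)
                matched_q.add(id(qtx))
    transcript = LevelStats("transcript", tp=len(matched_r),
                            fn=len(r_txs) - len(matched_r),
                            fp=len(q_txs) - len(matched_q))

    # locus level
    r_loci = _cluster_loci(ref)
    q_loci = _cluster_loci(query)
    r_by_key: dict[tuple, list[TranscriptModel]] = {}
    for tx in r_txs:
        r_by_key.setdefault((tx.contig, tx.strand), []).append(tx)

    tp_loci = sum(
        1 for locus in r_loci
        if any(transcript_match(qtx, rtx)
               for rtx in locus
               for qtx in q_by_key.get((rtx.contig, rtx.strand), [])))
    fp_loci = sum(
        1 for locus in q_loci
        if not any(transcript_match(qtx, rtx)
                   for qtx in _dedup(locus)
                   for rtx in r_by_key.get((qtx.contig, qtx.strand), [])))
    locus = LevelStats("locus", tp=tp_loci, fn=len(r_loci) - tp_loci,
                       fp=fp_loci)

    return [exon, locus, transcript]


def stats_to_tsv(stats: list[LevelStats]) -> str:
    lines = ["level\ttp\tfn\tfp\tsensitivity\tprecision"]
    for s in stats:
        lines.append("\t".join(str(v) for v in s.as_row()))
    return "\n".join(lines) + "\n"
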