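"""GFF3 / FASTA / splice-file I/O, CDS extraction and translation.

The GFF3 reader accepts nonstandard feature type names through a
:class:`~consanno.models.FeatureTypeMap`; everything downstream works on
CDS features only.
"""
from __future__ import annotations

import logging
import urllib.parse
from dataclasses import dataclass, field

from Bio.Seq import Seq

from .errors import DataError, Gff3ParseError, StructuralError
from .models import (
    AnnotationSet,
    CdsSegment,
    FeatureTypeMap,
    GeneModel,
    GenomeSequence,
    ProteinRecord,
    SpliceGroup,
    TranscriptModel,
    _slurp,
    protein_id,
    reverse_complement,
)

log = logging.getLogger(__name__)


def _parse_attributes(column: str, lineno: int) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for chunk in column.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        if "=" not in chunk:
            raise Gff3ParseError(f"line {lineno}: malformed attribute {chunk!r}")
        key, _, value = chunk.partition("=")
        attrs[key.strip()] = urllib.parse.unquote(value.strip())
    return attrs


@dataclass
class _Row:
    lineno: int
    contig: str
    ftype: str
    start: int  # already 0-based half-open
    end: int
    strand: str
    phase: int
    attrs: dict[str, str]


def _iter_rows(text: str, feature_map: FeatureTypeMap, skipped: dict[str, int]):
    for lineno, line in enumerate(text.splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        cols = line.rstrip("\n").split("\t")
        if len(cols) < 9:
            raise Gff3ParseError(f"line {lineno}: expected 9 columns, got {len(cols)}")
        contig, _src, ftype, start_s, end_s, _score, strand, phase_s, attr_col = cols[:9]
        role = feature_map.role_of(ftype)
        if role is None:
            skipped[ftype] = skipped.get(ftype, 0) + 1
            continue
        try:
            start1, end1 = int(start_s), int(end_s)
        except ValueError:
            raise Gff3ParseError(
                f"line {lineno}: non-integer coordinates {start_s!r}/{end_s!r}"
            ) from None
        if start1 < 1 or start1 > end1:
            raise Gff3ParseError(
                f"line {lineno}: bad coordinates start={start1} end={end1}")
        if phase_s in (".", ""):
            phase = 0
            if role == "cds":
                log.warning("line %d: CDS row without phase, assuming 0", lineno)
        else:
            try:
                phase = int(phase_s)
            except ValueError:
                raise Gff3ParseError(f"line {lineno}: bad phase {phase_s!r}") from None
        yield role, _Row(lineno, contig, ftype, start1 - 1, end1, strand,
                         phase, _parse_attributes(attr_col, lineno))


def parse_gff3(source, feature_map: FeatureTypeMap | None = None,
               source_name: str = "annotation") -> AnnotationSet:
    """Parse GFF3 text or file into an :class:`AnnotationSet`.

    Rows whose (mapped) type is neither gene, transcript nor cds are
    ignored with a logged count. Transcripts lacking a gene parent get a
    synthetic gene ``gene:<transcript_id>``.
    """
    feature_map = feature_map or FeatureTypeMap.default()
    text = _slurp(source)
    skipped: dict[str, int] = {}

    gene_rows: dict[str, _Row] = {}
    tx_rows: dict[str, _Row] = {}
    cds_by_tx: dict[str, list[_Row]] = {}

    for role, row in _iter_rows(text, feature_map, skipped):
        if role == "gene":
            gid = row.attrs.get("ID")
            if gid is None:
                raise Gff3ParseError(f"line {row.lineno}: gene row without ID")
            if gid in gene_rows:
                raise StructuralError(f"duplicate gene ID {gid!r} "
                                      f"(line {row.lineno})")
            gene_rows[gid] = row
        elif role == "transcript":
            tid = row.attrs.get("ID")
            if tid is None:
                raise Gff3ParseError(f"line {row.lineno}: transcript row without ID")
            if tid in tx_rows:
                raise StructuralError(f"duplicate transcript ID {tid!r} "
                                      f"(line {row.lineno})")
            tx_rows[tid] = row
        else:  # cds
            parent = row.attrs.get("Parent")
            if parent is None:
                raise StructuralError(f"line {row.lineno}: CDS row without Parent")
            if row.strand not in "+-":
                raise Gff3ParseError(
                    f"line {row.lineno}: CDS needs an explicit strand")
            for tid in parent.split(","):
                cds_by_tx.setdefault(tid, []).append(row)

    for tid in cds_by_tx:
        if tid not in tx_rows:
            raise StructuralError(
                f"CDS Parent {tid!r} does not name a known transcript")

    if skipped:
        log.info("%s: skipped unmapped feature rows: %s", source_name,
                 ", ".join(f"{k}×{v}" for k, v in sorted(skipped.items())))

    # assemble hierarchy
    genes_tx: dict[str, list[TranscriptModel]] = {}
    order: list[str] = list(gene_rows)
    for tid, row in tx_rows.items():
        rows = cds_by_tx.get(tid)
        if not rows:
            log.warning("transcript %s has no CDS rows; skipped", tid)
            continue
        segments = [CdsSegment(r.contig, r.start, r.end, r.strand, r.phase)
                    for r in rows]
        gid = row.attrs.get("Parent")
        if gid is None:
            gid = f"gene:{tid}"
        if gid not in gene_rows and gid not in genes_tx:
            order.append(gid)
        genes_tx.setdefault(gid, []).append(
            TranscriptModel(tid, gid, segments))

    ann = AnnotationSet(source_name=source_name,
                        origin_path=str(source) if "\n" not in str(source) else "")
    for gid in order:
        transcripts = genes_tx.get(gid)
        if not transcripts:
            log.warning("gene %s has no transcripts with CDS; skipped", gid)
            continue
        transcripts.sort(key=lambda t: t.transcript_id)
        ann.add(GeneModel(gid, source_name, transcripts))
    return ann


def translate_cds(segments, genome: GenomeSequence) -> str:
    """Translate a CDS segment chain into an amino-acid string.

    Segments are concatenated in genomic order, reverse-complemented on
    the minus strand, phase-trimmed, and translated with the standard
    genetic code. Trailing stop codons are removed; internal stops are
    left in the returned string for the caller to flag. Returns '' when
    the spliced sequence is shorter than one codon.
    """
    segs = sorted(segments, key=lambda s: s.start)
    seq = "".join(genome.fetch(s.contig, s.start, s.end) for s in segs)
    if segs[0].strand == "-":
        seq = reverse_complement(seq)
        phase = segs[-1].phase
    else:
        phase = segs[0].phase
    seq = seq[phase:]
    seq = seq[: len(seq) - len(seq) % 3]
    if len(seq) < 3:
        return ""
    aa = str(Seq(seq).translate())
    if aa.endswith("*"):
        aa = aa[:-1]
    return aa


@dataclass
class ProteomeResult:
    records: list[ProteinRecord]
    splice_groups: list[SpliceGroup]
    n_internal_stop: int = 0
    n_untranslatable: int = 0
    n_dropped_genes: int = 0

    def __iter__(self):  # allow (records, groups) unpacking
        return iter((self.records, self.splice_groups))


def extract_proteome(annotation: AnnotationSet,
                     genome: GenomeSequence) -> ProteomeResult:
    """Translate every isoform; exclude internal-stop isoforms; build
    splice groups for genes retaining >= 2 isoforms."""
    res = ProteomeResult([], [])
    for gid in annotation.genes:
        gene = annotation.genes[gid]
        gene_records: list[ProteinRecord] = []
        for tx in gene.transcripts:
            aa = translate_cds(tx.segments, genome)
            if not aa:
                res.n_untranslatable += 1
                log.warning("%s/%s: spliced CDS shorter than one codon; skipped",
                            gid, tx.transcript_id)
                continue
            if "*" in aa:
                res.n_internal_stop += 1
                log.warning("%s/%s: internal stop codon; isoform excluded",
                            gid, tx.transcript_id)
                continue
            gene_records.append(ProteinRecord(
                protein_id(annotation.source_name, gid, tx.transcript_id),
                aa, annotation.source_name, gid, tx.transcript_id))
        if not gene_records:
            res.n_dropped_genes += 1
            log.warning("%s: no translatable isoform; gene dropped", gid)
            continue
        res.records.extend(gene_records)
        if len(gene_records) >= 2:
            res.splice_groups.append(SpliceGroup(
                gid, tuple(r.protein_id for r in gene_records)))
    return res


# ---------------------------------------------------------------- writers

def _escape(value: str) -> str:
    return urllib.parse.quote(value, safe=":|.- _()+")


def _gene_rows(gene: GeneModel, gene_id: str, extra_attrs: dict[str, str],
               out: list[str], source_field: str) -> None:
    attrs = [f"ID={_escape(gene_id)}"]
    attrs += [f"{k}={_escape(v)}" for k, v in extra_attrs.items()]
    out.append("\t".join([gene.contig, source_field, "gene",
                          str(gene.start + 1), str(gene.end),
                          ".", gene.strand, ".", ";".join(attrs)]))
    for tx in gene.transcripts:
        tid = f"{gene_id}.{tx.transcript_id}" if gene_id != gene.gene_id \
            else tx.transcript_id
        out.append("\t".join([tx.contig, source_field, "mRNA",
                              str(tx.start + 1), str(tx.end), ".",
                              tx.strand, ".",
                              f"ID={_escape(tid)};Parent={_escape(gene_id)}"]))
        for seg in tx.segments:
            out.append("\t".join([seg.contig, source_field, "CDS",
                                  str(seg.start + 1), str(seg.end), ".",
                                  seg.strand, str(seg.phase),
                                  f"Parent={_escape(tid)}"]))


def annotation_to_gff3(annotation: AnnotationSet,
                       source_field: str | None = None) -> str:
    """Serialize an AnnotationSet as GFF3 (1-based inclusive)."""
    out = ["##gff-version 3"]
    for gid in annotation.genes:
        _gene_rows(annotation.genes[gid], gid, {}, out,
                   source_field or annotation.source_name)
    return "\n".join(out) + "\n"


def write_gff3(consensus, genome_ids=None) -> str:
    """Serialize a ConsensusAnnotation as GFF3 with provenance attributes.

    Gene ids are namespaced ``<source>.<gene_id>`` to stay unique across
    sources; each gene row carries ``source_annotation=`` and ``support=``.
    """
    out = ["##gff-version 3"]
    for cg in consensus.genes:
        gene = cg.representative
        if genome_ids is not None and gene.contig not in genome_ids:
            raise DataError(f"consensus gene {gene.gene_id} references "
                            f"unknown contig {gene.contig!r}")
        _gene_rows(gene, f"{cg.representative_source}.{gene.gene_id}",
                   {"source_annotation": cg.representative_source,
                    "support": cg.support.label()},
                   out, "consanno")
    return "\n".join(out) + "\n"


def write_fasta(records, handle_or_path) -> None:
    """Write protein records (or (id, seq) pairs) as FASTA."""
    own = isinstance(handle_or_path, (str, bytes)) or hasattr(handle_or_path, "__fspath__")
    fh = open(handle_or_path, "w") if own else handle_or_path
    try:
        for rec in records:
            pid, seq = (rec.protein_id, rec.sequence) if isinstance(rec, ProteinRecord) else rec
            fh.write(f">{pid}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i:i + 60] + "\n")
    finally:
        if own:
            fh.close()


def write_splice_file(groups, handle_or_path) -> None:
    """One gene per line, isoform protein ids separated by '; '."""
    own = isinstance(handle_or_path, (str, bytes)) or hasattr(handle_or_path, "__fspath__")
    fh = open(handle_or_path, "w") if own else handle_or_path
    try:
        for group in groups:
            fh.write("; ".join(group.isoform_protein_ids) + "\n")
    finally:
        if own:
            fh.close()


def read_protein_fasta(path, species_name: str) -> list[ProteinRecord]:
    """Read an (outgroup) proteome; ids are namespaced when not already."""
    from Bio import SeqIO

    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        parts = rec.id.split("|")
        if len(parts) == 3 and parts[0] == species_name:
            pid, gid, tid = rec.id, parts[1], parts[2]
        else:
            gid = tid = rec.id
            pid = protein_id(species_name, gid, tid)
        records.append(ProteinRecord(pid, str(rec.seq).rstrip("*"),
                                     species_name, gid, tid))
    return records
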