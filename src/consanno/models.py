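"""Shared domain model: genome sequences, gene structures, proteomes.

All coordinates are 0-based half-open internally; GFF3 readers/writers
convert to and from the 1-based inclusive convention at the boundary.
"""
from __future__ import annotations

import re
from collections.abc import Iterator, Mapping
from dataclasses import dataclass, field

from .errors import DataError, StructuralError

_NON_ACGT = re.compile(r"[^ACGT]")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

VALID_ROLES = ("gene", "transcript", "cds")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class GenomeSequence(Mapping):
    """Contig id -> uppercase nucleotide string (non-ACGT collapsed to N)."""

    def __init__(self, contigs: Mapping[str, str]):
        clean: dict[str, str] = {}
        for cid, seq in contigs.items():
            if not seq:
                raise DataError(f"contig {cid!r} has an empty sequence")
            if cid in clean:
                raise DataError(f"duplicate contig id {cid!r}")
            clean[cid] = _NON_ACGT.sub("N", seq.upper())
        self._contigs = clean

    @classmethod
    def from_fasta(cls, path) -> "GenomeSequence":
        from Bio import SeqIO

        return cls({rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")})

    def fetch(self, contig: str, start: int, end: int) -> str:
        seq = self._contigs[contig]
        if not (0 <= start < end <= len(seq)):
            raise DataError(
                f"slice [{start},{end}) out of bounds for contig {contig!r} "
                f"of length {len(seq)}"
            )
        return seq[start:end]

    def __getitem__(self, key: str) -> str:
        return self._contigs[key]

    def __iter__(self) -> Iterator[str]:
        return iter(self._contigs)

    def __len__(self) -> int:
        return len(self._contigs)


@dataclass(frozen=True)
class FeatureTypeMap:
    """Maps source feature names (case-insensitive) to canonical roles."""

    mapping: Mapping[str, str]

    def __post_init__(self):
        lowered: dict[str, str] = {}
        for name, role in self.mapping.items():
            key = name.strip().lower()
            if role not in VALID_ROLES:
                raise DataError(f"unknown role {role!r} for feature {name!r}")
            if key in lowered and lowered[key] != role:
                raise DataError(f"feature name {name!r} mapped to two roles")
            lowered[key] = role
        missing = [r for r in VALID_ROLES if r not in lowered.values()]
        if missing:
            raise DataError(f"feature map misses roles: {', '.join(missing)}")
        object.__setattr__(self, "mapping", lowered)

    def role_of(self, feature_name: str) -> str | None:
        return self.mapping.get(feature_name.strip().lower())

    @classmethod
    def default(cls) -> "FeatureTypeMap":
        return cls({"gene": "gene", "mrna": "transcript",
                    "transcript": "transcript", "cds": "cds"})

    @classmethod
    def from_tsv(cls, source) -> "FeatureTypeMap":
        """Read a 2-column TSV ``source_feature<TAB>role``; path or text."""
        text = _slurp(source)
        mapping: dict[str, str] = {}
        for i, line in enumerate(text.splitlines(), 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise DataError(f"feature map line {i}: expected 2 columns")
            mapping[parts[0]] = parts[1].strip().lower()
        return cls(mapping)


def _slurp(source) -> str:
    """Return text from a path-like or a literal text blob."""
    import os

    s = str(source)
    if "\n" not in s and os.path.exists(s):
        with open(s) as fh:
            return fh.read()
    return s


@dataclass(frozen=True, order=True)
class CdsSegment:
    contig: str
    start: int  # 0-based inclusive
    end: int    # 0-based exclusive
    strand: str
    phase: int = 0

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise StructuralError(
                f"bad segment coordinates [{self.start},{self.end})")
        if self.strand not in "+-":
            raise StructuralError(f"bad strand {self.strand!r}")
        if self.phase not in (0, 1, 2):
            raise StructuralError(f"bad phase {self.phase!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class TranscriptModel:
    transcript_id: str
    parent_gene_id: str
    segments: list[CdsSegment]

    def __post_init__(self):
        if not self.segments:
            raise StructuralError(f"transcript {self.transcript_id}: no CDS")
        segs = sorted(self.segments, key=lambda s: s.start)
        contig, strand = segs[0].contig, segs[0].strand
        for a, b in zip(segs, segs[1:]):
            if b.contig != contig or b.strand != strand:
                raise StructuralError(
                    f"transcript {self.transcript_id}: segments on mixed "
                    "contigs or strands")
            if b.start < a.end:
                raise StructuralError(
                    f"transcript {self.transcript_id}: overlapping CDS "
                    f"segments at {a.end}/{b.start}")
        self.segments = segs

    @property
    def contig(self) -> str:
        return self.segments[0].contig

    @property
    def strand(self) -> str:
        return self.segments[0].strand

    @property
    def start(self) -> int:
        return self.segments[0].start

    @property
    def end(self) -> int:
        return self.segments[-1].end

    @property
    def cds_length(self) -> int:
        return sum(s.length for s in self.segments)

    def introns(self) -> tuple[tuple[int, int], ...]:
        return tuple((a.end, b.start)
                     for a, b in zip(self.segments, self.segments[1:]))

    def chain_key(self) -> tuple:
        """Hashable identity of the segment chain (contig, strand, coords)."""
        return (self.contig, self.strand,
                tuple((s.start, s.end) for s in self.segments))


@dataclass
class GeneModel:
    gene_id: str
    source_name: str
    transcripts: list[TranscriptModel]

    def __post_init__(self):
        if not self.transcripts:
            raise StructuralError(f"gene {self.gene_id}: no transcripts")
        ids = [t.transcript_id for t in self.transcripts]
        if len(set(ids)) != len(ids):
            raise StructuralError(f"gene {self.gene_id}: duplicate transcript ids")

    @property
    def contig(self) -> str:
        return self.transcripts[0].contig

    @property
    def strand(self) -> str:
        return self.transcripts[0].strand

    @property
    def start(self) -> int:
        return min(t.start for t in self.transcripts)

    @property
    def end(self) -> int:
        return max(t.end for t in self.transcripts)

    @property
    def span(self) -> tuple[str, str, int, int]:
        return (self.contig, self.strand, self.start, self.end)

    @property
    def longest_cds(self) -> int:
        """Nucleotide CDS length of the longest isoform."""
        return max(t.cds_length for t in self.transcripts)


@dataclass
class AnnotationSet:
    """All gene models from one source annotation (one pseudo-species)."""

    source_name: str
    genes: dict[str, GeneModel] = field(default_factory=dict)
    origin_path: str = ""

    def add(self, gene: GeneModel) -> None:
        if gene.gene_id in self.genes:
            raise StructuralError(
                f"{self.source_name}: duplicate gene id {gene.gene_id!r}")
        self.genes[gene.gene_id] = gene

    def transcripts(self) -> Iterator[TranscriptModel]:
        for gene in self.genes.values():
            yield from gene.transcripts

    def __len__(self) -> int:
        return len(self.genes)


@dataclass(frozen=True)
class ProteinRecord:
    protein_id: str  # "<source>|<gene>|<transcript>"
    sequence: str
    source_name: str
    gene_id: str
    transcript_id: str

    def __post_init__(self):
        if not self.sequence:
            raise DataError(f"protein {self.protein_id}: empty sequence")
        if "*" in self.sequence:
            raise DataError(f"protein {self.protein_id}: internal stop")


@dataclass(frozen=True)
class SpliceGroup:
    """Isoform protein ids of one gene with alternative splicing (>= 2)."""

    gene_id: str
    isoform_protein_ids: tuple[str, ...]

    def __post_init__(self):
        if len(self.isoform_protein_ids) < 2:
            raise DataError(f"splice group {self.gene_id}: needs >= 2 isoforms")


def protein_id(source: str, gene: str, transcript: str) -> str:
    return f"{source}|{gene}|{transcript}"
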