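"""End-to-end orchestration: prepare -> infer/import -> extract -> report."""
from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

from . import annotation_io
from .consensus import (
    ConsensusAnnotation,
    assemble_consensus,
    compute_support,
    retain_genes,
    select_representative,
    write_reports,
)
from .errors import ConfigError
from .models import AnnotationSet, FeatureTypeMap, GenomeSequence, ProteinRecord
from .orthology import (
    EngineParams,
    ProteinDatabase,
    SpeciesTree,
    build_hogs,
    infer_ortholog_pairs,
    read_orthoxml,
)

log = logging.getLogger(__name__)


@dataclass
class SourceSpec:
    name: str
    gff3: str
    feature_map: str | None = None


@dataclass
class RunConfig:
    genome: str
    sources: list[SourceSpec]
    tree: str  # newick text or path
    outgroups: list[tuple[str, str]] = field(default_factory=list)
    orthoxml: str | None = None
    engine: EngineParams = field(default_factory=EngineParams)
    outgroup_evidence: str = "hog"
    priority: list[str] | None = None
    out_prefix: str = "consensus"

    def __post_init__(self):
        names = [s.name for s in self.sources]
        if len(self.sources) < 2:
            raise ConfigError("at least two source annotations are required")
        if len(set(names)) != len(names):
            raise ConfigError("source names must be unique")


def build_consensus(genome: GenomeSequence,
                    annotations: dict[str, AnnotationSet],
                    tree: SpeciesTree,
                    outgroup_proteomes: dict[str, list[ProteinRecord]],
                    engine: EngineParams | None = None,
                    orthoxml=None,
                    outgroup_evidence: str = "hog",
                    priority: list[str] | None = None,
                    source_order: list[str] | None = None
                    ) -> ConsensusAnnotation:
    """In-memory pipeline core shared by the CLI and the test suite."""
    proteomes: dict[str, list[ProteinRecord]] = {}
    splice_groups = {}
    for name, ann in annotations.items():
        result = annotation_io.extract_proteome(ann, genome)
        proteomes[name] = result.records
        splice_groups[name] = result.splice_groups
        log.info("%s: %d proteins, %d splice groups, %d internal-stop "
                 "isoforms excluded", name, len(result.records),
                 len(result.splice_groups), result.n_internal_stop)
    proteomes.update(outgroup_proteomes)
    db = ProteinDatabase(proteomes, splice_groups)

    pairs = None
    if orthoxml is not None:
        forest = read_orthoxml(orthoxml, tree)
    else:
        params = engine or EngineParams()
        pairs = infer_ortholog_pairs(db, params)
        log.info("inferred %d ortholog pairs (min_score=%d, min_cov=%.2f)",
                 len(pairs), params.min_score, params.min_cov)
        forest = build_hogs(pairs, tree, db)

    records = compute_support(forest, tree, outgroup_evidence=outgroup_evidence,
                              pairs=pairs if outgroup_evidence == "pairs" else None)
    retained = retain_genes(records)
    log.info("%d candidate HOGs at consensus node, %d retained",
             len(records), len(retained))
    source_order = source_order or sorted(annotations)
    representatives = [
        select_representative(rec, annotations, priority=priority,
                              source_order=source_order)
        for rec in retained]
    return assemble_consensus(retained, representatives, annotations, tree)


def run_pipeline(config: RunConfig) -> ConsensusAnnotation:
    """File-based pipeline: reads inputs, writes GFF3/FASTA/reports."""
    genome = GenomeSequence.from_fasta(config.genome)
    annotations: dict[str, AnnotationSet] = {}
    for spec in config.sources:
        fmap = (FeatureTypeMap.from_tsv(spec.feature_map)
                if spec.feature_map else FeatureTypeMap.default())
        annotations[spec.name] = annotation_io.parse_gff3(
            spec.gff3, fmap, source_name=spec.name)

    source_names = [s.name for s in config.sources]
    tree = SpeciesTree.from_newick(config.tree, source_names)
    outgroup_names = {name for name, _ in config.outgroups}
    unknown = sorted(outgroup_names - set(tree.outgroups))
    if unknown:
        raise ConfigError(
            f"outgroup proteomes not in tree: {', '.join(unknown)}")

    outgroup_proteomes = {
        name: annotation_io.read_protein_fasta(path, name)
        for name, path in config.outgroups}

    consensus = build_consensus(
        genome, annotations, tree, outgroup_proteomes,
        engine=config.engine, orthoxml=config.orthoxml,
        outgroup_evidence=config.outgroup_evidence,
        priority=config.priority, source_order=source_names)

    write_outputs(consensus, genome, annotations, config.out_prefix)
    return consensus


def write_outputs(consensus: ConsensusAnnotation, genome: GenomeSequence,
                  annotations: dict[str, AnnotationSet],
                  out_prefix: str) -> dict[str, str]:
    outdir = os.path.dirname(out_prefix)
    if outdir:
        os.makedirs(outdir, exist_ok=True)
    gff_path = f"{out_prefix}.gff3"
    with open(gff_path, "w") as fh:
        fh.write(annotation_io.write_gff3(consensus, genome_ids=set(genome)))
    faa_path = f"{out_prefix}.faa"
    records = []
    for cg in consensus.genes:
        gene = cg.representative
        for tx in gene.transcripts:
            aa = annotation_io.translate_cds(tx.segments, genome)
            pid = f"{cg.representative_source}.{gene.gene_id}.{tx.transcript_id}"
            records.append((pid, aa))
    annotation_io.write_fasta(records, faa_path)
    summary, detailed = write_reports(consensus, out_prefix)
    return {"gff3": gff_path, "faa": faa_path,
            "report": summary, "detailed_report": detailed}


def prepare_data(genome_path: str, sources: list[SourceSpec], out_dir: str,
                 tree: str | None = None) -> dict[str, list[str]]:
    """Emit the per-source DB-folder layout (FASTA + splice files, tree)."""
    genome = GenomeSequence.from_fasta(genome_path)
    os.makedirs(os.path.join(out_dir, "DB"), exist_ok=True)
    written: dict[str, list[str]] = {}
    for spec in sources:
        fmap = (FeatureTypeMap.from_tsv(spec.feature_map)
                if spec.feature_map else FeatureTypeMap.default())
        ann = annotation_io.parse_gff3(spec.gff3, fmap, source_name=spec.name)
        result = annotation_io.extract_proteome(ann, genome)
        fa = os.path.join(out_dir, "DB", f"{spec.name}.fa")
        annotation_io.write_fasta(result.records, fa)
        paths = [fa]
        if result.splice_groups:
            splice = os.path.join(out_dir, "DB", f"{spec.name}.splice")
            annotation_io.write_splice_file(result.splice_groups, splice)
            paths.append(splice)
        written[spec.name] = paths
    if tree is not None:
        from .models import _slurp

        tree_path = os.path.join(out_dir, "species_tree.nwk")
        with open(tree_path, "w") as fh:
            fh.write(_slurp(tree).strip() + "\n")
        written["tree"] = [tree_path]
    return written
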