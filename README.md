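# consanno

Consensus protein-coding gene annotation from multiple GFF3 sources.

Different annotation methods (ab initio, RNAseq-based, homology-based)
disagree; `consanno` combines them by treating each source annotation as a
pseudo-species in an orthology inference over a user-supplied species tree.
Gene models that land in the same hierarchical orthologous group (HOG) at the
tree node joining the sources are candidate consensus genes. A candidate is
retained when it is predicted by **at least two sources**, or by a single
source **with a detected ortholog in an outgroup species**. Each retained
group contributes one representative model (longest CDS by default, or the
highest-ranking source with `--priority`) together with **all** of its
isoforms.

## What's inside

| module | role |
| --- | --- |
| `consanno.annotation_io` | GFF3/FASTA/splice-file I/O, feature-type remapping, CDS translation |
| `consanno.orthology` | species tree, Smith–Waterman scoring (BLOSUM62, affine gaps), strict reciprocal-best-hit inference, bottom-up HOG construction, orthoXML ingestion |
| `consanno.consensus` | support vectors, retention rule, representative selection, reports |
| `consanno.evaluation` | GffCompare-style sensitivity/precision at exon, locus and transcript levels (100-nt terminal tolerance, 80% single-exon overlap) |
| `consanno.simulate` | synthetic genomes, truth annotations, corrupted sources, diverged outgroup proteomes with known ground truth |
| `consanno.pipeline` / `consanno.cli` | orchestration and the `consanno` command |

The built-in orthology engine is a deliberately simple stand-in (local
alignment + strict RBH + connected components per tree node). For
full-fidelity interop, a HOG forest computed by an external orthology tool
can be supplied as orthoXML with `--orthoxml`, which bypasses the engine.

## CLI

```bash
# generate a synthetic data set with known ground truth
consanno simulate --n-genes 50 --seed 1 --out sim/

# write the per-source protein DB folder (FASTA + splice files)
consanno prepare-data --genome sim/genome.fa \
    --source src1=sim/src1.gff3 --source src2=sim/src2.gff3 \
    --tree sim/tree.nwk --out oma_folder/

# run the full pipeline with the built-in engine
consanno run --genome sim/genome.fa \
    --source src1=sim/src1.gff3 --source src2=sim/src2.gff3 \
    --source src3=sim/src3.gff3 \
    --outgroup out1=sim/out1.faa --outgroup out2=sim/out2.faa \
    --tree sim/tree.nwk --out results/consensus

# or import a precomputed HOG forest instead
consanno run ... --orthoxml HierarchicalGroups.orthoxml

# score an annotation against a reference
consanno evaluate --query results/consensus.gff3 --ref sim/truth.gff3
```

Sources with nonstandard GFF3 feature names take a 2-column TSV mapping
(`--source name=path:featuremap.tsv`) whose rows are
`source_feature<TAB>gene|transcript|cds`. The species tree must contain one
internal node whose leaf set is exactly the source names; all other leaves
are outgroup species.

Outputs: `<prefix>.gff3`, `<prefix>.faa`, `<prefix>_report.txt` (summary
counts per support combination and per representative source) and
`<prefix>_detailed_report.txt` (TSV, one row per consensus gene with 0/1
support columns per source and outgroup).

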