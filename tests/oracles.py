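"""Independent brute-force oracles.

These deliberately avoid the package's implementation paths: the
aligner oracle is a plain three-state Gotoh DP, the translation oracle
splices by string slicing and translates with its own codon dict, and
the evaluation oracle is naive all-pairs matching.
"""
from __future__ import annotations

import functools

# -- affine-gap local alignment (Gotoh), gap length k costs open+(k-1)*ext

NEG = float("-inf")


@functools.lru_cache(maxsize=1)
def _blosum62():
    from Bio.Align import substitution_matrices

    return substitution_matrices.load("BLOSUM62")


def _sub(x: str, y: str) -> float:
    if x == "X" or y == "X":
        return 0.0
    return _blosum62()[x, y]


def sw_affine_bruteforce(a: str, b: str, gap_open: int = 11,
                         gap_ext: int = 1) -> int:
    n, m = len(a), len(b)
    best = 0.0
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a (moving along b)
    F = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] - gap_open, E[i][j - 1] - gap_ext)
            F[i][j] = max(H[i - 1][j] - gap_open, F[i - 1][j] - gap_ext)
            H[i][j] = max(0.0, H[i - 1][j - 1] + _sub(a[i - 1], b[j - 1]),
                          E[i][j], F[i][j])
            best = max(best, H[i][j])
    return int(best)


# -- splice-then-translate

_CODE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

_RC = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def naive_translate(segments, genome) -> str:
    segs = sorted(segments, key=lambda s: s.start)
    spliced = "".join(genome[s.contig][s.start:s.end] for s in segs)
    if segs[0].strand == "-":
        spliced = "".join(_RC[c] for c in reversed(spliced))
        spliced = spliced[segs[-1].phase:]
    else:
        spliced = spliced[segs[0].phase:]
    aa = []
    for i in range(0, len(spliced) - len(spliced) % 3, 3):
        codon = spliced[i:i + 3]
        aa.append(_CODE.get(codon, "X"))
    out = "".join(aa)
    return out[:-1] if out.endswith("*") else out


# -- naive all-pairs evaluation

def _naive_tx_match(q, r) -> bool:
    if q.contig != r.contig or q.strand != r.strand:
        return False
    qi = [(s.end, t.start) for s, t in zip(q.segments, q.segments[1:])]
    ri = [(s.end, t.start) for s, t in zip(r.segments, r.segments[1:])]
    if (len(q.segments) > 1) != (len(r.segments) > 1):
        return False
    if len(q.segments) > 1:
        return (qi == ri and abs(q.segments[0].start - r.segments[0].start) <= 100
                and abs(q.segments[-1].end - r.segments[-1].end) <= 100)
    ov = min(q.segments[0].end, r.segments[0].end) - \
        max(q.segments[0].start, r.segments[0].start)
    return ov >= 0.8 * (r.segments[0].end - r.segments[0].start)


def naive_evaluate(query_ann, ref_ann):
    """Returns {(level): (tp, fn, fp)} by exhaustive comparison."""
    def dedup(txs):
        seen, out = set(), []
        for t in txs:
            k = (t.contig, t.strand, tuple((s.start, s.end) for s in t.segments))
            if k not in seen:
                seen.add(k)
                out.append(t)
        return out

    q_txs = dedup([t for g in query_ann.genes.values() for t in g.transcripts])
    r_txs = [t for g in ref_ann.genes.values() for t in g.transcripts]

    q_ex = {(s.contig, s.strand, s.start, s.end) for t in q_txs for s in t.segments}
    r_ex = {(s.contig, s.strand, s.start, s.end) for t in r_txs for s in t.segments}
    exon = (len(q_ex & r_ex), len(r_ex - q_ex), len(q_ex - r_ex))

    r_matched = [any(_naive_tx_match(q, r) for q in q_txs) for r in r_txs]
    q_matched = [any(_naive_tx_match(q, r) for r in r_txs) for q in q_txs]
    transcript = (sum(r_matched), len(r_txs) - sum(r_matched),
                  len(q_txs) - sum(q_matched))

    def loci(ann):
        genes = sorted(ann.genes.values(),
                       key=lambda g: (g.contig, g.strand, g.start, g.end))
        out, cur, end, key = [], [], -1, None
        for g in genes:
            k = (g.contig, g.strand)
            if cur and k == key and g.start < end:
                cur.append(g)
                end = max(end, g.end)
            else:
                if cur:
                    out.append(cur)
                cur, key, end = [g], k, g.end
        if cur:
            out.append(cur)
        return out

    r_loci = loci(ref_ann)
    q_loci = loci(query_ann)
    tp = sum(1 for locus in r_loci
             if any(_naive_tx_match(q, r) for g in locus
                    for r in g.transcripts for q in q_txs))
    fp = sum(1 for locus in q_loci
             if not any(_naive_tx_match(q, r)
                        for q in dedup([t for g in locus for t in g.transcripts])
                        for r in r_txs))
    locus = (tp, len(r_loci) - tp, fp)
    return {"exon": exon, "locus": locus, "transcript": transcript}
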