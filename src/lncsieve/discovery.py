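"""Candidate discovery: spliced mapping, the lncRNA gate, origin classes,
antisense-UTR detection and the internal-priming screen.

The mapper is a seed-and-chain spliced aligner built for clean full-length
transcripts: exact k-mer seeds (k=15 by default) are collected per chromosome
and strand, merged into gapless anchors along diagonals, chained collinearly,
and the chain is refined into exon blocks; a genomic gap of at least 20 nt
between blocks is treated as an intron and the exact splice point is chosen
to maximize matches. A placement is accepted only at >=99% identity and
>=99% coverage, mirroring the stringent full-length cDNA mapping contract;
failure to place is a value (None), not an error.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from lncsieve import intervals as iv
from lncsieve.models import (
    GeneModel,
    GenomeInterval,
    GenomeMapping,
    GenomeRecord,
    LncRNACandidate,
    TranscriptRecord,
    revcomp,
)

DEFAULT_K = 15
MIN_INTRON = 20


# ---------------------------------------------------------------------------
# Seed index


class KmerIndex:
    """Exact k-mer positions for every chromosome of a genome."""

    def __init__(self, genome: GenomeRecord, k: int = DEFAULT_K):
        self.k = k
        self.genome = genome
        self.index: dict[str, dict[str, list[int]]] = {}
        for chrom, seq in genome.chrom_sequences.items():
            d: dict[str, list[int]] = {}
            for i in range(len(seq) - k + 1):
                kmer = seq[i : i + k]
                if "N" in kmer:
                    continue
                d.setdefault(kmer, []).append(i)
            self.index[chrom] = d

    def hits(self, chrom: str, seq: str) -> list[tuple[int, int]]:
        """(query_pos, target_pos) for every exact k-mer match."""
        d = self.index[chrom]
        k = self.k
        out = []
        for q in range(len(seq) - k + 1):
            for t in d.get(seq[q : q + k], ()):
                out.append((q, t))
        return out


# ---------------------------------------------------------------------------
# Chaining and refinement


def _anchors(hits: list[tuple[int, int]], k: int) -> list[tuple[int, int, int]]:
    """Merge seed hits on the same diagonal into maximal gapless anchors.

    Returns (qstart, qend, tstart) triples sorted by query position.
    """
    by_diag: dict[int, list[int]] = {}
    for q, t in hits:
        by_diag.setdefault(t - q, []).append(q)
    anchors = []
    for diag, qs in by_diag.items():
        qs.sort()
        start = prev = qs[0]
        for q in qs[1:]:
            if q <= prev + k:  # overlapping/adjacent seeds extend the run
                prev = q
            else:
                anchors.append((start, prev + k, start + diag))
                start = prev = q
        anchors.append((start, prev + k, start + diag))
    anchors.sort(key=lambda a: (a[0], a[2]))
    return anchors


def _chain(anchors: list[tuple[int, int, int]]) -> list[tuple[int, int, int]]:
    """Best collinear chain of anchors by total anchor length (DP, O(n^2))."""
    n = len(anchors)
    if n == 0:
        return []
    best = [a[1] - a[0] for a in anchors]
    prev = [-1] * n
    for i in range(n):
        qi, _, ti = anchors[i]
        for j in range(i):
            qj, qe, tj = anchors[j]
            te = tj + (qe - qj)
            if qe <= qi + 5 and te <= ti + 5 and ti - te < 10**6:
                cand = best[j] + anchors[i][1] - anchors[i][0]
                if cand > best[i]:
                    best[i] = cand
                    prev[i] = j
    end = max(range(n), key=lambda i: best[i])
    chain = []
    while end != -1:
        chain.append(anchors[end])
        end = prev[end]
    return chain[::-1]


def _match_count(a: str, b: str) -> int:
    return sum(1 for x, y in zip(a, b) if x == y and x != "N")


@dataclass
class _Block:
    qstart: int
    qend: int
    tstart: int  # genomic start

    @property
    def tend(self) -> int:
        return self.tstart + (self.qend - self.qstart)


def _refine(
    chain: list[tuple[int, int, int]],
    seq: str,
    target: str,
    min_intron: int,
) -> Optional[list[_Block]]:
    """Turn a chain into exon blocks covering the whole query.

    Query gaps between anchors on the same diagonal are absorbed (mismatch
    runs); genomic gaps >= min_intron nt beyond the query gap open an intron,
    with the splice point placed to maximize matches.
    """
    blocks = [_Block(q0, q1, t0) for q0, q1, t0 in chain]
    # extend first/last block to the query ends (gapless)
    b = blocks[0]
    ext = min(b.qstart, b.tstart)
    blocks[0] = _Block(b.qstart - ext, b.qend, b.tstart - ext)
    if blocks[0].qstart > 0:
        return None  # ran off the chromosome start
    b = blocks[-1]
    ext = min(len(seq) - b.qend, len(target) - b.tend)
    blocks[-1] = _Block(b.qstart, b.qend + ext, b.tstart)
    if blocks[-1].qend < len(seq):
        return None
    merged = [blocks[0]]
    for b in blocks[1:]:
        p = merged[-1]
        gq = b.qstart - p.qend
        gt = b.tstart - p.tend
        if gq < 0 or gt < 0:
            # overlapping anchors: trim the incoming block
            trim = max(-gq, -gt)
            b = _Block(b.qstart + trim, b.qend, b.tstart + trim)
            gq = b.qstart - p.qend
            gt = b.tstart - p.tend
            if gq < 0 or gt < 0 or b.qstart >= b.qend:
                continue
        if gt - gq >= min_intron:
            # intron: split the gq unaligned query bases at the best point
            gap = seq[p.qend : b.qstart]
            left = target[p.tend : p.tend + gq]
            right = target[b.tstart - gq : b.tstart]
            best_s, best_m = 0, -1
            for s in range(gq + 1):
                m = _match_count(gap[:s], left[:s]) + _match_count(
                    gap[s:], right[gq - s :]
                )
                if m > best_m:
                    best_m, best_s = m, s
            merged[-1] = _Block(p.qstart, p.qend + best_s, p.tstart)
            merged.append(_Block(b.qstart - (gq - best_s), b.qend, b.tstart - (gq - best_s)))
        else:
            # same exon: absorb the gap gaplessly (only if collinear)
            if gq != gt:
                return None  # indel within an exon: not representable gaplessly
            merged[-1] = _Block(p.qstart, b.qend, p.tstart)
    return merged


def map_transcript(
    transcript: TranscriptRecord,
    genome: GenomeRecord,
    index: Optional[KmerIndex] = None,
    k: int = DEFAULT_K,
    min_identity: float = 0.99,
    min_coverage: float = 0.99,
    min_intron: int = MIN_INTRON,
) -> Optional[GenomeMapping]:
    """Best spliced placement of a transcript, or None below the 99/99 gate."""
    if index is None:
        index = KmerIndex(genome, k=k)
    best: Optional[GenomeMapping] = None
    for strand in ("+", "-"):
        seq = transcript.sequence if strand == "+" else revcomp(transcript.sequence)
        for chrom in sorted(genome.chrom_sequences):
            target = genome.chrom_sequences[chrom]
            hits = index.hits(chrom, seq)
            if not hits:
                continue
            chain = _chain(_anchors(hits, index.k))
            if not chain:
                continue
            blocks = _refine(chain, seq, target, min_intron)
            if not blocks:
                continue
            matches = sum(
                _match_count(seq[b.qstart : b.qend], target[b.tstart : b.tend])
                for b in blocks
            )
            aligned = sum(b.qend - b.qstart for b in blocks)
            identity = matches / aligned if aligned else 0.0
            coverage = aligned / len(seq)
            mapping = GenomeMapping(
                transcript_id=transcript.transcript_id,
                blocks=[
                    GenomeInterval(chrom, b.tstart, b.tend, strand) for b in blocks
                ],
                identity=identity,
                coverage=coverage,
                strand=strand,
                score=matches,
            )
            if best is None or mapping.score > best.score:
                best = mapping
    if best is None:
        return None
    if best.identity >= min_identity and best.coverage >= min_coverage:
        return best
    return None


# ---------------------------------------------------------------------------
# The lncRNA gate


def gate_lncrna(
    mapping: GenomeMapping,
    transcript: TranscriptRecord,
    genes: list[GeneModel],
    length_min: int = 200,
    slop_nt: int = 5,
) -> bool:
    """True iff the mapped transcript qualifies as an lncRNA candidate.

    Rejected when shorter than length_min, when its exonic footprint lies
    exclusively within known protein-coding (CDS) exons, or when it lies
    within CDS plus UTR exons while actually overlapping CDS. Containment
    tolerates up to slop_nt of footprint outside the annotation, absorbing
    the few-nt splice-boundary wobble of motif-free spliced mappings.
    """
    if len(transcript.sequence) < length_min:
        return False
    fp = mapping.footprint
    chrom = mapping.chrom
    cds = [c.pair for g in genes if g.span.chrom == chrom for c in g.cds]
    utr = [
        u.pair
        for g in genes
        if g.span.chrom == chrom
        for u in g.utr5 + g.utr3
    ]
    if iv.total_length(iv.subtract(fp, cds)) <= slop_nt:
        return False
    if (
        iv.total_length(iv.subtract(fp, cds + utr)) <= slop_nt
        and iv.overlap_length(fp, cds) > 0
    ):
        return False
    return True


def classify_origin(
    mapping: GenomeMapping,
    genes: list[GeneModel],
    proximity_nt: int = 1000,
) -> tuple[str, Optional[str]]:
    """Assign one origin class and (where applicable) a host gene.

    utr_only / intron_only / mixed relative to the gene with the largest
    overlap (ties broken by lexicographic gene id); near_gene when within
    proximity_nt of the nearest gene without overlap; intergenic otherwise.
    """
    fp = mapping.footprint
    chrom = mapping.chrom
    span = (mapping.start, mapping.end)
    overlapping = []
    for g in genes:
        if g.span.chrom != chrom:
            continue
        ov = iv.overlap_length(fp, [g.span.pair])
        if ov > 0:
            overlapping.append((-ov, g.gene_id, g))
    if overlapping:
        overlapping.sort(key=lambda t: (t[0], t[1]))
        g = overlapping[0][2]
        if iv.contained_in(fp, [u.pair for u in g.utr5 + g.utr3]):
            return "utr_only", g.gene_id
        if iv.contained_in(fp, [i.pair for i in g.introns]):
            return "intron_only", g.gene_id
        return "mixed", g.gene_id
    best_d, best_g = None, None
    for g in genes:
        if g.span.chrom != chrom:
            continue
        d = iv.gap_to([g.span.pair], span)
        if d >= 0 and (best_d is None or d < best_d or (d == best_d and g.gene_id < best_g)):
            best_d, best_g = d, g.gene_id
    if best_d is not None and best_d < proximity_nt:
        return "near_gene", best_g
    return "intergenic", None


def detect_antisense_utr(
    candidate: LncRNACandidate, genes: list[GeneModel]
) -> Optional[str]:
    """Gene id of an antisense-UTR target, if the configuration matches.

    The candidate must run antisense to a gene, overlap that gene only within
    its UTR intervals, and no CDS exon of any gene may overlap the candidate
    footprint on either strand.
    """
    fp = candidate.mapping.footprint
    chrom = candidate.mapping.chrom
    for g in genes:
        if g.span.chrom == chrom and iv.overlap_length(fp, [c.pair for c in g.cds]) > 0:
            return None
    for g in genes:
        if g.span.chrom != chrom or g.strand == candidate.mapping.strand:
            continue
        utr = [u.pair for u in g.utr5 + g.utr3]
        ov_gene = iv.overlap_length(fp, [g.span.pair])
        if ov_gene > 0 and ov_gene == iv.overlap_length(fp, utr):
            return g.gene_id
    return None


def internal_priming_filter(
    mapping: GenomeMapping,
    genome: GenomeRecord,
    window: int = 50,
    a_frac: float = 0.65,
    a_run: int = 8,
) -> bool:
    """Flag likely internal-priming artifacts.

    The genomic window immediately 3' of the mapped end (reverse-complement
    logic on the minus strand) is A-rich: A-fraction >= a_frac over the
    window, or a run of >= a_run consecutive A. A window truncated by the
    chromosome end is evaluated as-is.
    """
    chrom_seq = genome.chrom_sequences[mapping.chrom]
    if mapping.strand == "+":
        win = chrom_seq[mapping.end : mapping.end + window]
    else:
        win = revcomp(chrom_seq[max(0, mapping.start - window) : mapping.start])
    if not win:
        return False
    if win.count("A") / len(win) >= a_frac:
        return True
    run = best = 0
    for c in win:
        run = run + 1 if c == "A" else 0
        best = max(best, run)
    return best >= a_run


def exon_summary(candidates: list[LncRNACandidate]) -> dict:
    """Single-exon vs spliced partition with the single-exon percentage."""
    single = sum(1 for c in candidates if c.exon_count == 1)
    spliced = len(candidates) - single
    total = len(candidates)
    return {
        "single_exon": single,
        "spliced": spliced,
        "total": total,
        "percent_single_exon": round(100.0 * single / total, 1) if total else "n/a",
    }
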