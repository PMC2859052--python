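"""Selection signals on candidate lncRNAs.

Two independent lines of evidence are computed here:

* Primary-sequence conservation contrast: the global-alignment identity of an
  lncRNA ortholog pair is compared with equal-length flanking buffer regions
  immediately up- and downstream. Functional lncRNAs are expected to be more
  conserved than their flanks (often the flanks have no detectable homology
  at all).

* Coding-potential assessment: each transcript is conceptually translated in
  all six frames; the longest ORF per frame is kept; ORF pairs with
  significant protein-level local-alignment homology are scored with the
  Nei-Gojobori (1986) counting estimator of Ka/Ks with Jukes-Cantor
  correction. Ratios in the neutral band (0.5-1.5) argue against protein-
  coding selection, whereas bona fide coding orthologs sit well below 0.5.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from math import log
from typing import Optional

from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq

from lncsieve.alignment import (
    AlignmentResult,
    GlobalAlignment,
    global_align,
    local_align,
)
from lncsieve.models import revcomp

__all__ = [
    "GlobalAlignment",
    "FlankContrast",
    "ORFRecord",
    "KaKsResult",
    "global_align",
    "six_frame_orfs",
    "protein_homology_gate",
    "kaks_ng86",
    "kaks_contrast",
    "classify_band",
]

_CODON_TABLE = dict(standard_dna_table.forward_table)
for _stop in standard_dna_table.stop_codons:
    _CODON_TABLE[_stop] = "*"

BANDS = {"purifying": (0.0, 0.5), "neutral": (0.5, 1.5), "diversifying": (1.5, float("inf"))}


@dataclass
class FlankContrast:
    """Identity of an lncRNA ortholog pair versus its flanking buffers."""

    candidate_id: str
    lnc_identity: float  # percent
    flank_identity: Optional[float]  # percent; None when no flank homology
    flank_conserved: bool
    truncated: bool = False  # a buffer ran into a chromosome end

    def __post_init__(self) -> None:
        if (self.flank_identity is None) == self.flank_conserved:
            raise ValueError("flank_identity must be absent iff flank not conserved")


@dataclass
class ORFRecord:
    """The longest open reading frame of one translation frame."""

    frame: int  # +1, +2, +3, -1, -2, -3
    nt_start: int  # offsets on the forward transcript, half-open
    nt_end: int
    protein: str

    @property
    def length_aa(self) -> int:
        return len(self.protein)


@dataclass
class KaKsResult:
    """Nei-Gojobori (1986) per-site substitution estimates for one codon pair."""

    ka: Optional[float]
    ks: Optional[float]
    ratio: Optional[float]  # None when Ks == 0 (undefined) or saturated
    s_sites: float
    n_sites: float
    sd: float
    nd: float
    undefined: bool = False  # Ks == 0
    saturated: bool = False  # Jukes-Cantor correction impossible (p >= 3/4)
    role: str = ""  # "lncRNA" | "parent"


# ---------------------------------------------------------------------------
# Flanking-conservation contrast


def flank_contrast(
    candidate_id: str,
    source_interval,
    ortholog_hit,
    genome_a,
    genome_b,
    synteny,
    pad: int = 5000,
    evalue_max: float = 0.01,
) -> FlankContrast:
    """Identity of the lncRNA ortholog pair versus equal-length flanking buffers.

    Buffers immediately up- and downstream of the source interval, each of the
    lncRNA's own length, are projected through the synteny map and searched in
    the target genome; a buffer counts as conserved when its best local hit
    reaches e < evalue_max. flank_identity is the mean global-alignment
    identity of the conserved buffers and is absent when neither is conserved.
    Buffers running past a chromosome end are truncated (and recorded).
    """
    from lncsieve.models import GenomeInterval
    from lncsieve.orthology import find_ortholog

    if ortholog_hit.target_interval is None:
        raise ValueError(f"{candidate_id}: no ortholog interval for flank contrast")
    L = len(source_interval)
    chrom_len = genome_a.chrom_length(source_interval.chrom)
    truncated = False
    buffers = []
    up_start = source_interval.start - L
    if up_start < 0:
        truncated = True
        up_start = 0
    if source_interval.start > up_start:
        buffers.append(GenomeInterval(source_interval.chrom, up_start, source_interval.start))
    down_end = source_interval.end + L
    if down_end > chrom_len:
        truncated = True
        down_end = chrom_len
    if down_end > source_interval.end:
        buffers.append(GenomeInterval(source_interval.chrom, source_interval.end, down_end))

    identities = []
    for buf in buffers:
        bseq = genome_a.fetch(buf)
        hit = find_ortholog(
            f"{candidate_id}:flank", bseq, buf, genome_b, synteny, pad=pad,
            evalue_loose=evalue_max,
        )
        if hit.homologous_at_1e2 and hit.target_interval is not None:
            tseq = genome_b.fetch(hit.target_interval)
            identities.append(global_align(bseq, tseq).identity)

    a_seq = genome_a.fetch(source_interval)
    b_seq = genome_b.fetch(ortholog_hit.target_interval)
    lnc_identity = global_align(a_seq, b_seq).identity
    conserved = bool(identities)
    return FlankContrast(
        candidate_id=candidate_id,
        lnc_identity=lnc_identity,
        flank_identity=(sum(identities) / len(identities)) if conserved else None,
        flank_conserved=conserved,
        truncated=truncated,
    )


# ---------------------------------------------------------------------------
# Six-frame ORF scan


def _orfs_in_frame(seq: str, offset: int) -> list[tuple[int, int]]:
    """(start, end) of every ATG..stop ORF in one forward frame (end excludes stop)."""
    out = []
    i = offset
    n = len(seq)
    start = None
    while i + 3 <= n:
        codon = seq[i : i + 3]
        aa = _CODON_TABLE.get(codon)
        if start is None:
            if codon == "ATG":
                start = i
        elif aa == "*":
            out.append((start, i))
            start = None
        i += 3
    return out


def six_frame_orfs(sequence: str, mode: str = "atg") -> list[ORFRecord]:
    """Longest ORF per frame across all six conceptual translations.

    mode="atg" (default): ATG-initiated, stop-terminated, stop excluded.
    mode="stop_free": longest stop-free codon stretch per frame (no ATG
    requirement), as an alternative ORF definition.
    Frames without an ORF are omitted. Ties go to the smallest start offset.
    Coordinates are on the forward transcript.
    """
    if len(sequence) < 3:
        raise ValueError("sequence shorter than one codon")
    out: list[ORFRecord] = []
    rc = revcomp(sequence)
    n = len(sequence)
    for sense, seq in ((1, sequence), (-1, rc)):
        for off in range(3):
            if mode == "atg":
                spans = _orfs_in_frame(seq, off)
            elif mode == "stop_free":
                spans = _stop_free_spans(seq, off)
            else:
                raise ValueError(f"unknown ORF mode {mode!r}")
            spans = [s for s in spans if s[1] > s[0]]
            if not spans:
                continue
            best = max(spans, key=lambda se: (se[1] - se[0], -se[0]))
            s, e = best
            prot = "".join(_CODON_TABLE[seq[i : i + 3]] for i in range(s, e, 3))
            if sense == 1:
                nt_start, nt_end = s, e
            else:
                nt_start, nt_end = n - e, n - s
            out.append(ORFRecord(frame=sense * (off + 1), nt_start=nt_start, nt_end=nt_end, protein=prot))
    return out


def _stop_free_spans(seq: str, offset: int) -> list[tuple[int, int]]:
    out = []
    i = offset
    start = i
    n = len(seq)
    while i + 3 <= n:
        if _CODON_TABLE.get(seq[i : i + 3]) == "*":
            out.append((start, i))
            start = i + 3
        i += 3
    out.append((start, i))
    return out


# ---------------------------------------------------------------------------
# Protein homology gate


def protein_homology_gate(
    orf_a: ORFRecord,
    orf_b: ORFRecord,
    evalue_max: float = 0.01,
) -> bool:
    """True iff the two ORF proteins share significant local homology.

    Local alignment under BLOSUM62 with affine gaps; significance at
    e-value < evalue_max. Proteins shorter than 10 aa violate the
    precondition and raise ValueError (callers skip such pairs).
    """
    if orf_a.length_aa < 10 or orf_b.length_aa < 10:
        raise ValueError(
            f"protein_homology_gate requires >=10 aa (got {orf_a.length_aa}, {orf_b.length_aa})"
        )
    hit = _protein_hit(orf_a, orf_b)
    return hit.evalue < evalue_max


def _protein_hit(orf_a: ORFRecord, orf_b: ORFRecord) -> AlignmentResult:
    return local_align(
        orf_a.protein, orf_b.protein, protein=True, gap_open=-11, gap_extend=-1
    )


# ---------------------------------------------------------------------------
# NG86 Ka/Ks


def _codon_sites(codon: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site counts of one codon.

    Each position contributes fractions summing to 1; changes to stop codons
    count as nonsynonymous, so S + N = 3 exactly.
    """
    aa = _CODON_TABLE[codon]
    s = 0.0
    for pos in range(3):
        syn = 0
        for alt in "ACGT":
            if alt == codon[pos]:
                continue
            mutant = codon[:pos] + alt + codon[pos + 1 :]
            if _CODON_TABLE[mutant] == aa:
                syn += 1
        s += syn / 3.0
    return s, 3.0 - s


def _pathway_diffs(c1: str, c2: str) -> tuple[float, float]:
    """Pathway-averaged (synonymous, nonsynonymous) differences for one codon pair.

    All orders of introducing the differing positions are enumerated; pathways
    passing through a stop codon are excluded (unless every pathway does, in
    which case all are kept).
    """
    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    if not diff_pos:
        return 0.0, 0.0
    pathways = []
    for order in itertools.permutations(diff_pos):
        cur = c1
        sd = nd = 0
        through_stop = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if _CODON_TABLE[nxt] == "*":
                through_stop = True
            if _CODON_TABLE[nxt] == _CODON_TABLE[cur]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        pathways.append((through_stop, sd, nd))
    valid = [(s, n) for stop, s, n in pathways if not stop]
    if not valid:
        valid = [(s, n) for _, s, n in pathways]
    sd = sum(s for s, _ in valid) / len(valid)
    nd = sum(n for _, n in valid) / len(valid)
    return sd, nd


def _jukes_cantor(p: float) -> Optional[float]:
    if p >= 0.75:
        return None
    if p == 0.0:
        return 0.0
    return -0.75 * log(1.0 - 4.0 * p / 3.0)


def kaks_ng86(cds_a: str, cds_b: str, role: str = "") -> KaKsResult:
    """Nei-Gojobori (1986) Ka/Ks for a gapless codon alignment.

    Site counts are averaged over both sequences; multi-position codon
    differences are averaged over all minimal mutational pathways (pathways
    through stop codons excluded); proportions are Jukes-Cantor corrected.
    The ratio is flagged undefined when Ks = 0 and saturated when a
    proportion reaches 3/4.
    """
    if len(cds_a) != len(cds_b):
        raise ValueError("NG86 requires equal-length sequences")
    if len(cds_a) % 3 != 0 or len(cds_a) == 0:
        raise ValueError("NG86 requires non-empty sequences of whole codons")
    s_a = n_a = s_b = n_b = 0.0
    sd = nd = 0.0
    for i in range(0, len(cds_a), 3):
        ca, cb = cds_a[i : i + 3], cds_b[i : i + 3]
        if _CODON_TABLE.get(ca, "*") == "*" or _CODON_TABLE.get(cb, "*") == "*":
            raise ValueError(f"internal stop or ambiguous codon at position {i}")
        xs, xn = _codon_sites(ca)
        s_a += xs
        n_a += xn
        xs, xn = _codon_sites(cb)
        s_b += xs
        n_b += xn
        ds, dn = _pathway_diffs(ca, cb)
        sd += ds
        nd += dn
    s_sites = (s_a + s_b) / 2.0
    n_sites = (n_a + n_b) / 2.0
    ps = sd / s_sites if s_sites > 0 else 0.0
    pn = nd / n_sites if n_sites > 0 else 0.0
    ks = _jukes_cantor(ps)
    ka = _jukes_cantor(pn)
    saturated = ks is None or ka is None
    undefined = (not saturated) and ks == 0.0
    ratio = None
    if not saturated and not undefined:
        ratio = ka / ks
    return KaKsResult(
        ka=ka,
        ks=ks,
        ratio=ratio,
        s_sites=s_sites,
        n_sites=n_sites,
        sd=sd,
        nd=nd,
        undefined=undefined,
        saturated=saturated,
        role=role,
    )


def classify_band(ratio: Optional[float]) -> str:
    """purifying < 0.5 <= neutral <= 1.5 < diversifying; None -> 'undefined'."""
    if ratio is None:
        return "undefined"
    if ratio < 0.5:
        return "purifying"
    if ratio <= 1.5:
        return "neutral"
    return "diversifying"


# ---------------------------------------------------------------------------
# Codon alignment from a protein alignment


def codon_pair_from_protein_alignment(
    orf_a: ORFRecord,
    orf_b: ORFRecord,
    nt_a: str,
    nt_b: str,
    hit: Optional[AlignmentResult] = None,
) -> tuple[str, str]:
    """Back-translate the gapless columns of a protein local alignment.

    nt_a/nt_b are the full transcripts the ORFs came from; the returned codon
    strings are equal length, whole codons, no gaps (gapped columns dropped).
    """
    if hit is None:
        hit = _protein_hit(orf_a, orf_b)
    cds_a = _orf_nt(orf_a, nt_a)
    cds_b = _orf_nt(orf_b, nt_b)
    ia, ib = hit.query_start, hit.target_start
    out_a, out_b = [], []
    for x, y in zip(hit.aligned_query, hit.aligned_target):
        if x != "-" and y != "-":
            out_a.append(cds_a[3 * ia : 3 * ia + 3])
            out_b.append(cds_b[3 * ib : 3 * ib + 3])
        if x != "-":
            ia += 1
        if y != "-":
            ib += 1
    return "".join(out_a), "".join(out_b)


def _orf_nt(orf: ORFRecord, transcript: str) -> str:
    sub = transcript[orf.nt_start : orf.nt_end]
    return revcomp(sub) if orf.frame < 0 else sub


# ---------------------------------------------------------------------------
# Ka/Ks contrast table


def kaks_contrast(
    lnc_pairs: list[tuple[str, str, str]],
    parent_pairs: list[tuple[str, str, str]],
    evalue_max: float = 0.01,
) -> list[dict]:
    """Contrast Ka/Ks of lncRNA ORF pairs against their parent-gene CDS pairs.

    lnc_pairs: (candidate_id, transcript_a, transcript_b) nucleotide sequences.
    parent_pairs: (candidate_id, cds_a, cds_b) codon-aligned parent CDS.
    For each lncRNA the reported value comes from the highest-scoring ORF pair
    that passes the protein homology gate; candidates with no gated pair are
    reported as "no ORF homology".
    """
    parents = {cid: (a, b) for cid, a, b in parent_pairs}
    rows = []
    for cid, ta, tb in lnc_pairs:
        row: dict = {"candidate_id": cid}
        best = None
        orfs_a = [o for o in six_frame_orfs(ta) if o.length_aa >= 10]
        orfs_b = [o for o in six_frame_orfs(tb) if o.length_aa >= 10]
        for oa in orfs_a:
            for ob in orfs_b:
                hit = _protein_hit(oa, ob)
                if hit.evalue < evalue_max:
                    if best is None or hit.score > best[0].score:
                        best = (hit, oa, ob)
        if best is None:
            row.update(kaks_lnc=None, band_lnc="no ORF homology")
        else:
            hit, oa, ob = best
            ca, cb = codon_pair_from_protein_alignment(oa, ob, ta, tb, hit)
            try:
                res = kaks_ng86(ca, cb, role="lncRNA")
                row.update(
                    kaks_lnc=res.ratio,
                    band_lnc=classify_band(res.ratio),
                    result_lnc=res,
                )
            except ValueError:
                row.update(kaks_lnc=None, band_lnc="undefined")
        if cid in parents:
            pa, pb = parents[cid]
            res = kaks_ng86(pa, pb, role="parent")
            row.update(
                kaks_parent=res.ratio,
                band_parent=classify_band(res.ratio),
                result_parent=res,
            )
        else:
            row.update(kaks_parent=None, band_parent="no parent")
        rows.append(row)
    return rows
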