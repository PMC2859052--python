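"""Synteny-guided orthology: locate and score cross-species counterparts.

A candidate's genomic interval is projected through the pairwise synteny map
into the target genome (linear interpolation inside the covering block,
orientation-aware, padded generously), the candidate sequence is locally
aligned against that window on both strands, and the best hit is scored at
two significance thresholds: a strict one (e < 1e-6) for calling sequence
homology in summary tallies, and a loose one (e < 0.01) for ortholog
deduction ahead of the evolutionary analyses. Preservation across additional
species is summarized as a fixed-order code over {H, M, D, C}.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from lncsieve.alignment import AlignmentResult, local_align
from lncsieve.models import (
    GenomeInterval,
    GenomeRecord,
    LncRNACandidate,
    SyntenyBlock,
    revcomp,
)

EVALUE_STRICT = 1e-6
EVALUE_LOOSE = 1e-2
DEFAULT_PAD = 5000

SPECIES_ORDER = "HMDC"  # human, mouse, dog, cow


@dataclass
class OrthologHit:
    """Best syntenic cross-species match for one candidate."""

    candidate_id: str
    species_tag: str
    hit: Optional[AlignmentResult]
    syntenic: bool
    homologous_at_1e6: bool
    homologous_at_1e2: bool
    target_interval: Optional[GenomeInterval] = None  # genomic span of the hit

    def __post_init__(self) -> None:
        if self.homologous_at_1e6 and not self.homologous_at_1e2:
            raise ValueError("homology at 1e-6 implies homology at 1e-2")


def syntenic_window(
    interval: GenomeInterval,
    blocks: list[SyntenyBlock],
    pad: int = DEFAULT_PAD,
    target_chrom_length: Optional[int] = None,
) -> Optional[GenomeInterval]:
    """Project an interval into the target genome through its synteny block.

    Endpoints are linearly interpolated within the covering block (the block
    with the largest overlap when several touch), mirrored for inverted
    blocks, extended by pad on both sides and clipped to chromosome bounds.
    Returns None when no block covers the interval.
    """
    best = None
    best_ov = 0
    for b in blocks:
        if b.source.chrom != interval.chrom:
            continue
        ov = min(interval.end, b.source.end) - max(interval.start, b.source.start)
        if ov > best_ov:
            best_ov, best = ov, b
    if best is None:
        return None
    src, tgt = best.source, best.target
    scale = len(tgt) / len(src)
    lo = max(interval.start, src.start)
    hi = min(interval.end, src.end)
    if best.orientation == "same":
        t_lo = tgt.start + (lo - src.start) * scale
        t_hi = tgt.start + (hi - src.start) * scale
    else:
        t_lo = tgt.end - (hi - src.start) * scale
        t_hi = tgt.end - (lo - src.start) * scale
    start = int(t_lo) - pad
    end = int(t_hi) + pad
    start = max(0, start)
    if target_chrom_length is not None:
        end = min(end, target_chrom_length)
    if end <= start:
        return None
    return GenomeInterval(tgt.chrom, start, end)


def find_ortholog(
    candidate_id: str,
    candidate_seq: str,
    source_interval: GenomeInterval,
    target_genome: GenomeRecord,
    synteny: list[SyntenyBlock],
    pad: int = DEFAULT_PAD,
    evalue_strict: float = EVALUE_STRICT,
    evalue_loose: float = EVALUE_LOOSE,
) -> OrthologHit:
    """Align a candidate against its syntenic window and score homology.

    Both strands of the window are searched; the best hit wins (ties by
    higher identity, then smaller target start).
    """
    window = syntenic_window(source_interval, synteny, pad=pad)
    if window is not None:
        end = min(window.end, target_genome.chrom_length(window.chrom))
        window = GenomeInterval(window.chrom, window.start, end) if end > window.start else None
    if window is None:
        return OrthologHit(candidate_id, target_genome.species_tag, None, False, False, False)
    wseq = target_genome.fetch(window)
    best_hit = None
    best_iv = None
    for strand in ("+", "-"):
        seq = wseq if strand == "+" else revcomp(wseq)
        hit = local_align(candidate_seq, seq)
        if hit.score <= 0:
            continue
        if strand == "+":
            t0 = window.start + hit.target_start
            t1 = window.start + hit.target_end
        else:
            t0 = window.end - hit.target_end
            t1 = window.end - hit.target_start
        iv_ = GenomeInterval(window.chrom, t0, t1, strand) if t1 > t0 else None
        key = (hit.score, hit.identity, -t0)
        if best_hit is None or key > (best_hit.score, best_hit.identity, -best_iv.start):
            best_hit, best_iv = hit, iv_
    if best_hit is None:
        return OrthologHit(candidate_id, target_genome.species_tag, None, True, False, False)
    return OrthologHit(
        candidate_id=candidate_id,
        species_tag=target_genome.species_tag,
        hit=best_hit,
        syntenic=True,
        homologous_at_1e6=best_hit.evalue < evalue_strict,
        homologous_at_1e2=best_hit.evalue < evalue_loose,
        target_interval=best_iv,
    )


def preservation_profile(
    home_species: str,
    hits: dict[str, OrthologHit],
) -> str:
    """Fixed-order preservation code over {H, M, D, C}.

    One letter per species where the ortholog search found homology at the
    loose threshold; the home species is always included. Species outside
    the canonical four are appended alphabetically.
    """
    present = {home_species}
    for tag, hit in hits.items():
        if hit.homologous_at_1e2:
            present.add(tag)
    code = [s for s in SPECIES_ORDER if s in present]
    code += sorted(s for s in present if s not in SPECIES_ORDER)
    return "".join(code)


def classify_conservation(
    candidates: list[LncRNACandidate],
    hits: dict[str, OrthologHit],
) -> dict:
    """Summary tallies: homology split, genomic-location split, spliced split."""
    with_hom = sum(
        1
        for c in candidates
        if (h := hits.get(c.transcript_id)) is not None and h.homologous_at_1e6
    )
    coding_region = sum(
        1 for c in candidates if c.origin_class in ("utr_only", "intron_only", "mixed")
    )
    spliced = sum(1 for c in candidates if c.exon_count > 1)
    n = len(candidates)
    return {
        "total": n,
        "with_significant_homology": with_hom,
        "without_significant_homology": n - with_hom,
        "protein_coding_region": coding_region,
        "non_protein_coding_region": n - coding_region,
        "spliced": spliced,
        "non_spliced": n - spliced,
    }
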