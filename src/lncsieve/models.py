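"""Core domain types shared across the pipeline.

Coordinates are 0-based half-open everywhere inside the package; conversion to
and from 1-based formats (GFF3) happens only at I/O boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from lncsieve import intervals as iv

VALID_BASES = set("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class ValidationError(ValueError):
    """Raised when a domain object violates its invariants."""


@dataclass(frozen=True)
class GenomeInterval:
    """A stranded genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in ("+", "-"):
            raise ValidationError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def pair(self) -> tuple[int, int]:
        return (self.start, self.end)

    def overlaps(self, other: "GenomeInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class GenomeRecord:
    """One species' genome: a short species tag and chromosome sequences."""

    species_tag: str
    chrom_sequences: dict[str, str]

    def __post_init__(self) -> None:
        for name, seq in self.chrom_sequences.items():
            if not seq:
                raise ValidationError(f"empty sequence for chromosome {name!r}")
            bad = set(seq) - VALID_BASES
            if bad:
                raise ValidationError(
                    f"chromosome {name!r} contains invalid characters {sorted(bad)}"
                )

    def fetch(self, interval: GenomeInterval) -> str:
        """Strand-aware sequence of an interval (reverse-complemented on '-')."""
        seq = self.chrom_sequences[interval.chrom]
        if interval.end > len(seq):
            raise ValidationError(
                f"interval {interval} beyond end of {interval.chrom} ({len(seq)} nt)"
            )
        s = seq[interval.start : interval.end]
        return revcomp(s) if interval.strand == "-" else s

    def chrom_length(self, chrom: str) -> int:
        return len(self.chrom_sequences[chrom])


@dataclass
class GeneModel:
    """A protein-coding gene model with exon/CDS/UTR structure."""

    gene_id: str
    transcript_id: str
    span: GenomeInterval
    exons: list[GenomeInterval]
    cds: list[GenomeInterval] = field(default_factory=list)
    utr5: list[GenomeInterval] = field(default_factory=list)
    utr3: list[GenomeInterval] = field(default_factory=list)
    cancer_flag: bool = False

    def validate(self) -> None:
        pairs = [e.pair for e in self.exons]
        if sorted(pairs) != pairs:
            raise ValidationError(f"{self.gene_id}: exons not sorted")
        if iv.total_length(pairs) != sum(len(e) for e in self.exons):
            raise ValidationError(f"{self.gene_id}: exons overlap")
        exonic = pairs
        for kind, feats in (("CDS", self.cds), ("5'UTR", self.utr5), ("3'UTR", self.utr3)):
            for f in feats:
                if not iv.contained_in([f.pair], exonic):
                    raise ValidationError(
                        f"{self.gene_id}: {kind} {f.start}-{f.end} outside exons"
                    )
        footprint = [f.pair for f in self.cds + self.utr5 + self.utr3]
        if iv.total_length(footprint) != iv.total_length(exonic) or iv.total_length(
            footprint
        ) != sum(len(f) for f in self.cds + self.utr5 + self.utr3):
            raise ValidationError(
                f"{self.gene_id}: CDS/UTR features do not partition the exonic footprint"
            )

    @property
    def strand(self) -> str:
        return self.span.strand

    @property
    def introns(self) -> list[GenomeInterval]:
        out = []
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start > a.end:
                out.append(
                    GenomeInterval(self.span.chrom, a.end, b.start, self.span.strand)
                )
        return out

    def cds_length(self) -> int:
        return sum(len(c) for c in self.cds)


@dataclass
class TranscriptRecord:
    """A full-length transcript sequence from one species."""

    transcript_id: str
    sequence: str
    species_tag: str = ""

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise ValidationError(f"{self.transcript_id}: empty sequence")
        bad = set(self.sequence) - VALID_BASES
        if bad:
            raise ValidationError(
                f"{self.transcript_id}: invalid characters {sorted(bad)}"
            )


@dataclass(frozen=True)
class SyntenyBlock:
    """A pairwise synteny block between a source and a target genome."""

    source: GenomeInterval
    target: GenomeInterval
    orientation: str = "same"  # same | inverted

    def __post_init__(self) -> None:
        if self.orientation not in ("same", "inverted"):
            raise ValidationError(f"invalid orientation {self.orientation!r}")


@dataclass
class CancerGeneSet:
    """Gene identifiers annotated to cancer (a CGMIM-like reference set)."""

    gene_ids: set[str]
    source_label: str = "cancer-gene fixture"


@dataclass
class GenomeMapping:
    """Spliced placement of a transcript on a genome."""

    transcript_id: str
    blocks: list[GenomeInterval]
    identity: float
    coverage: float
    strand: str
    score: float = 0.0

    @property
    def chrom(self) -> str:
        return self.blocks[0].chrom

    @property
    def start(self) -> int:
        return self.blocks[0].start

    @property
    def end(self) -> int:
        return self.blocks[-1].end

    @property
    def exon_count(self) -> int:
        return len(self.blocks)

    @property
    def footprint(self) -> list[tuple[int, int]]:
        return [b.pair for b in self.blocks]

    def mapped_length(self) -> int:
        return sum(len(b) for b in self.blocks)


ORIGIN_CLASSES = ("utr_only", "intron_only", "mixed", "near_gene", "intergenic")


@dataclass
class LncRNACandidate:
    """A transcript that passed the lncRNA gate, with its annotations."""

    transcript_id: str
    mapping: GenomeMapping
    origin_class: str = ""
    host_gene_id: Optional[str] = None
    exon_count: int = 1
    priming_flag: bool = False
    antisense_target: Optional[str] = None
    conservation: Optional[object] = None  # OrthologHit, set by orthology stage
    preservation_code: str = ""
    lnc_identity: Optional[float] = None  # percent
    flank_identity: Optional[float] = None  # percent, None = flank not conserved
    structure_flag: Optional[bool] = None

    def __post_init__(self) -> None:
        if self.origin_class and self.origin_class not in ORIGIN_CLASSES:
            raise ValidationError(f"unknown origin class {self.origin_class!r}")
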