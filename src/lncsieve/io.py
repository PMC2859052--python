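"""Readers and writers for every on-disk format the pipeline touches.

Formats: FASTA (genomes, transcripts), GFF3 and BED12 (gene models), a
tab-separated synteny map, a two-column cancer-gene list, and the candidate
report (TSV plus a machine-readable JSON twin). GFF3 is 1-based inclusive and
BED is 0-based half-open on disk; both are converted to the package's internal
0-based half-open convention on read.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Optional

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from lncsieve import intervals as iv
from lncsieve.models import (
    CancerGeneSet,
    GeneModel,
    GenomeInterval,
    GenomeMapping,
    GenomeRecord,
    LncRNACandidate,
    SyntenyBlock,
    TranscriptRecord,
    ValidationError,
)


class ParseError(ValueError):
    pass


# ---------------------------------------------------------------------------
# FASTA

def _normalize(seq: str) -> str:
    return seq.upper().replace("U", "T")


def read_genome_fasta(path: str | Path, species_tag: str = "") -> GenomeRecord:
    """Read a genome FASTA; sequences are uppercased and U mapped to T."""
    chroms: dict[str, str] = {}
    for i, rec in enumerate(SeqIO.parse(str(path), "fasta"), start=1):
        seq = _normalize(str(rec.seq))
        if not rec.id:
            raise ParseError(f"{path}: record {i} has an empty header")
        if not seq:
            raise ParseError(f"{path}: record {i} ({rec.id!r}) is empty")
        if rec.id in chroms:
            raise ParseError(f"{path}: duplicate chromosome name {rec.id!r}")
        chroms[rec.id] = seq
    if not chroms:
        raise ParseError(f"{path}: no FASTA records found")
    return GenomeRecord(species_tag=species_tag, chrom_sequences=chroms)


def write_genome_fasta(genome: GenomeRecord, path: str | Path) -> None:
    recs = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in genome.chrom_sequences.items()
    ]
    SeqIO.write(recs, str(path), "fasta")


def read_transcripts_fasta(path: str | Path, species_tag: str = "") -> list[TranscriptRecord]:
    out = []
    for i, rec in enumerate(SeqIO.parse(str(path), "fasta"), start=1):
        seq = _normalize(str(rec.seq))
        if not seq:
            raise ParseError(f"{path}: record {i} ({rec.id!r}) is empty")
        out.append(TranscriptRecord(rec.id, seq, species_tag))
    return out


def write_transcripts_fasta(transcripts: Iterable[TranscriptRecord], path: str | Path) -> None:
    recs = [SeqRecord(Seq(t.sequence), id=t.transcript_id, description="") for t in transcripts]
    SeqIO.write(recs, str(path), "fasta")


# ---------------------------------------------------------------------------
# Gene annotations (GFF3 / BED12)

def _derive_utrs(
    gene_id: str,
    strand: str,
    chrom: str,
    exons: list[tuple[int, int]],
    cds: list[tuple[int, int]],
) -> tuple[list[GenomeInterval], list[GenomeInterval]]:
    """Split exon-minus-CDS into 5'/3' UTR by position relative to the CDS."""
    utr = iv.subtract(exons, cds)
    if not cds:
        return [], [GenomeInterval(chrom, s, e, strand) for s, e in utr]
    cds_start = min(s for s, _ in cds)
    cds_end = max(e for _, e in cds)
    five, three = [], []
    for s, e in utr:
        if e <= cds_start:
            (five if strand == "+" else three).append((s, e))
        elif s >= cds_end:
            (three if strand == "+" else five).append((s, e))
        else:  # UTR chunk between CDS pieces: attach by midpoint side
            mid = (s + e) // 2
            near5 = mid < (cds_start + cds_end) // 2
            if strand == "-":
                near5 = not near5
            (five if near5 else three).append((s, e))
    mk = lambda pairs: [GenomeInterval(chrom, s, e, strand) for s, e in pairs]
    return mk(five), mk(three)


def _build_gene(
    gene_id: str,
    transcript_id: str,
    chrom: str,
    strand: str,
    exons: list[tuple[int, int]],
    cds: list[tuple[int, int]],
    utr5: Optional[list[tuple[int, int]]] = None,
    utr3: Optional[list[tuple[int, int]]] = None,
) -> GeneModel:
    exons = iv.merge(exons)
    cds = iv.merge(cds)
    if not iv.contained_in(cds, exons):
        raise ValidationError(f"gene {gene_id}: CDS outside exons")
    if utr5 is None and utr3 is None:
        u5, u3 = _derive_utrs(gene_id, strand, chrom, exons, cds)
    else:
        u5 = [GenomeInterval(chrom, s, e, strand) for s, e in iv.merge(utr5 or [])]
        u3 = [GenomeInterval(chrom, s, e, strand) for s, e in iv.merge(utr3 or [])]
    span = GenomeInterval(chrom, exons[0][0], exons[-1][1], strand)
    gene = GeneModel(
        gene_id=gene_id,
        transcript_id=transcript_id,
        span=span,
        exons=[GenomeInterval(chrom, s, e, strand) for s, e in exons],
        cds=[GenomeInterval(chrom, s, e, strand) for s, e in cds],
        utr5=u5,
        utr3=u3,
    )
    gene.validate()
    return gene


def _read_gff3(path: str | Path) -> list[GeneModel]:
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    genes: list[GeneModel] = []
    for mrna in db.features_of_type("mRNA"):
        gene_id = mrna.attributes.get("Parent", [mrna.id])[0]
        exons, cds, u5, u3 = [], [], [], []
        explicit_utr = False
        for child in db.children(mrna.id):
            pair = (child.start - 1, child.end)  # GFF3 1-based inclusive -> half-open
            if child.featuretype == "exon":
                exons.append(pair)
            elif child.featuretype == "CDS":
                cds.append(pair)
            elif child.featuretype == "five_prime_UTR":
                u5.append(pair)
                explicit_utr = True
            elif child.featuretype == "three_prime_UTR":
                u3.append(pair)
                explicit_utr = True
        if not exons:
            raise ParseError(f"{path}: mRNA {mrna.id} has no exons")
        genes.append(
            _build_gene(
                gene_id,
                mrna.id,
                mrna.seqid,
                mrna.strand,
                exons,
                cds,
                u5 if explicit_utr else None,
                u3 if explicit_utr else None,
            )
        )
    genes.sort(key=lambda g: (g.span.chrom, g.span.start, g.gene_id))
    return genes


def _read_bed12(path: str | Path) -> list[GeneModel]:
    genes = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise ParseError(f"{path}:{ln}: expected 12 BED columns, got {len(f)}")
            chrom, start, end, name = f[0], int(f[1]), int(f[2]), f[3]
            strand = f[5]
            thick_s, thick_e = int(f[6]), int(f[7])
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            starts = [int(x) for x in f[11].rstrip(",").split(",")]
            if len(sizes) != int(f[9]) or len(starts) != int(f[9]):
                raise ParseError(f"{path}:{ln}: blockCount mismatch")
            exons = [(start + o, start + o + sz) for o, sz in zip(starts, sizes)]
            cds = iv.intersect(exons, [(thick_s, thick_e)]) if thick_e > thick_s else []
            genes.append(_build_gene(name, name, chrom, strand, exons, cds))
    genes.sort(key=lambda g: (g.span.chrom, g.span.start, g.gene_id))
    return genes


def read_annotation(path: str | Path, dialect: str = "gff3") -> list[GeneModel]:
    """Read gene models from GFF3 or BED12 into internal half-open coordinates."""
    if dialect == "gff3":
        return _read_gff3(path)
    if dialect == "bed12":
        return _read_bed12(path)
    raise ValueError(f"unknown annotation dialect {dialect!r}")


def write_gff3(genes: Iterable[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            c, st = g.span.chrom, g.span.strand
            row = lambda ftype, s, e, fid, parent: fh.write(
                f"{c}\tlncsieve\t{ftype}\t{s + 1}\t{e}\t.\t{st}\t.\t{fid}"
                + (f";Parent={parent}" if parent else "")
                + "\n"
            )
            row("gene", g.span.start, g.span.end, f"ID={g.gene_id}", "")
            row("mRNA", g.span.start, g.span.end, f"ID={g.transcript_id}", g.gene_id)
            for x in g.exons:
                row("exon", x.start, x.end, f"ID={g.transcript_id}.exon.{x.start}", g.transcript_id)
            for x in g.cds:
                row("CDS", x.start, x.end, f"ID={g.transcript_id}.cds.{x.start}", g.transcript_id)
            for x in g.utr5:
                row("five_prime_UTR", x.start, x.end, f"ID={g.transcript_id}.u5.{x.start}", g.transcript_id)
            for x in g.utr3:
                row("three_prime_UTR", x.start, x.end, f"ID={g.transcript_id}.u3.{x.start}", g.transcript_id)


# ---------------------------------------------------------------------------
# Synteny map

def read_synteny_map(path: str | Path) -> list[SyntenyBlock]:
    """Read a tab-separated synteny map.

    Columns: chromA startA endA chromB startB endB orientation(same|inverted).
    Blocks must be non-overlapping on the source genome.
    """
    blocks = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) != 7:
                raise ParseError(f"{path}:{ln}: expected 7 columns, got {len(f)}")
            ca, sa, ea, cb, sb, eb, orient = f
            sa, ea, sb, eb = int(sa), int(ea), int(sb), int(eb)
            if sa >= ea:
                raise ParseError(f"{path}:{ln}: startA >= endA")
            if sb >= eb:
                raise ParseError(f"{path}:{ln}: startB >= endB")
            blocks.append(
                SyntenyBlock(
                    GenomeInterval(ca, sa, ea),
                    GenomeInterval(cb, sb, eb),
                    orient,
                )
            )
    blocks.sort(key=lambda b: (b.source.chrom, b.source.start))
    for a, b in zip(blocks, blocks[1:]):
        if a.source.chrom == b.source.chrom and b.source.start < a.source.end:
            raise ParseError(
                f"{path}: synteny blocks overlap on source at "
                f"{a.source.chrom}:{b.source.start}"
            )
    return blocks


def write_synteny_map(blocks: Iterable[SyntenyBlock], path: str | Path) -> None:
    with open(path, "w") as fh:
        for b in blocks:
            fh.write(
                f"{b.source.chrom}\t{b.source.start}\t{b.source.end}\t"
                f"{b.target.chrom}\t{b.target.start}\t{b.target.end}\t{b.orientation}\n"
            )


# ---------------------------------------------------------------------------
# Cancer gene list

def read_cancer_genes(path: str | Path) -> CancerGeneSet:
    """Two-column TSV: gene_id <tab> source label."""
    ids: set[str] = set()
    label = "cancer-gene fixture"
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            ids.add(f[0])
            if len(f) > 1 and f[1]:
                label = f[1]
    return CancerGeneSet(gene_ids=ids, source_label=label)


def write_cancer_genes(genes: CancerGeneSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for gid in sorted(genes.gene_ids):
            fh.write(f"{gid}\t{genes.source_label}\n")


# ---------------------------------------------------------------------------
# Candidate report

REPORT_COLUMNS = [
    "id",
    "origin_class",
    "exon_count",
    "priming_flag",
    "preservation_code",
    "lnc_identity",
    "flank_identity",
    "identity_summary",
    "structure_flag",
]


def _fmt_pct(x: Optional[float]) -> str:
    return "" if x is None else f"{x:.1f}%"


def render_identity(lnc: Optional[float], flank: Optional[float]) -> str:
    """Table-style rendering, e.g. '87.9% (17.2%)' or '64.3% (not conserved)'."""
    if lnc is None:
        return ""
    inner = "not conserved" if flank is None else f"{flank:.1f}%"
    return f"{lnc:.1f}% ({inner})"


def write_candidate_report(candidates: list[LncRNACandidate], path: str | Path) -> None:
    """Write the candidate table as TSV plus a machine-readable JSON twin."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("\t".join(REPORT_COLUMNS) + "\n")
        for c in candidates:
            fh.write(
                "\t".join(
                    [
                        c.transcript_id,
                        c.origin_class,
                        str(c.exon_count),
                        str(c.priming_flag).lower(),
                        c.preservation_code,
                        _fmt_pct(c.lnc_identity),
                        (
                            "not conserved"
                            if c.lnc_identity is not None and c.flank_identity is None
                            else _fmt_pct(c.flank_identity)
                        ),
                        render_identity(c.lnc_identity, c.flank_identity),
                        "" if c.structure_flag is None else str(c.structure_flag).lower(),
                    ]
                )
                + "\n"
            )
    payload = [candidate_to_dict(c) for c in candidates]
    with open(path.with_suffix(".json"), "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")


def candidate_to_dict(c: LncRNACandidate) -> dict:
    return {
        "id": c.transcript_id,
        "origin_class": c.origin_class,
        "host_gene_id": c.host_gene_id,
        "exon_count": c.exon_count,
        "priming_flag": c.priming_flag,
        "antisense_target": c.antisense_target,
        "preservation_code": c.preservation_code,
        "lnc_identity": c.lnc_identity,
        "flank_identity": c.flank_identity,
        "structure_flag": c.structure_flag,
        "mapping": {
            "chrom": c.mapping.chrom,
            "strand": c.mapping.strand,
            "identity": round(c.mapping.identity, 6),
            "coverage": round(c.mapping.coverage, 6),
            "blocks": [[b.start, b.end] for b in c.mapping.blocks],
        },
    }


def candidate_from_dict(d: dict) -> LncRNACandidate:
    m = d["mapping"]
    blocks = [
        GenomeInterval(m["chrom"], s, e, m["strand"]) for s, e in m["blocks"]
    ]
    mapping = GenomeMapping(
        transcript_id=d["id"],
        blocks=blocks,
        identity=m["identity"],
        coverage=m["coverage"],
        strand=m["strand"],
    )
    return LncRNACandidate(
        transcript_id=d["id"],
        mapping=mapping,
        origin_class=d["origin_class"],
        host_gene_id=d.get("host_gene_id"),
        exon_count=d["exon_count"],
        priming_flag=d["priming_flag"],
        antisense_target=d.get("antisense_target"),
        preservation_code=d.get("preservation_code", ""),
        lnc_identity=d.get("lnc_identity"),
        flank_identity=d.get("flank_identity"),
        structure_flag=d.get("structure_flag"),
    )


def read_candidate_report(json_path: str | Path) -> list[LncRNACandidate]:
    with open(json_path) as fh:
        return [candidate_from_dict(d) for d in json.load(fh)]
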