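"""Pipeline orchestration: run every stage over a dataset directory.

Stages run in order: map -> gate -> origin -> antisense -> priming ->
orthology -> preservation -> flank contrast -> Ka/Ks -> structure ->
enrichment -> summary. Each stage persists its results into the report
bundle (TSV for people, JSON for machines), so every stage can also be
re-run standalone from the previous stage's output. Re-running with the
same inputs and seed produces byte-identical bundles: all randomness is
seeded per candidate and no output carries timestamps.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from lncsieve import io as lio
from lncsieve.discovery import (
    KmerIndex,
    classify_origin,
    detect_antisense_utr,
    exon_summary,
    gate_lncrna,
    internal_priming_filter,
    map_transcript,
)
from lncsieve.enrichment import build_table, enrichment_report
from lncsieve.models import GenomeInterval, LncRNACandidate
from lncsieve.orthology import (
    OrthologHit,
    classify_conservation,
    find_ortholog,
    preservation_profile,
)
from lncsieve.selection import flank_contrast, kaks_contrast
from lncsieve.structure import evaluate_pair


class PipelineError(RuntimeError):
    def __init__(self, stage: str, record: str, message: str):
        super().__init__(f"[stage {stage}] {record}: {message}")
        self.stage = stage
        self.record = record


@dataclass
class PipelineConfig:
    """Thresholds and the seed; serializable to/from YAML."""

    length_min: int = 200
    identity_min: float = 0.99
    coverage_min: float = 0.99
    evalue_strict: float = 1e-6
    evalue_loose: float = 1e-2
    proximity_nt: int = 1000
    priming_window: int = 50
    priming_a_frac: float = 0.65
    priming_a_run: int = 8
    z_min: float = 2.0
    sci_min: float = 0.7
    synteny_pad: int = 5000
    n_shuffles: int = 60
    gate_slop_nt: int = 5
    seed: int = 0

    def validate(self) -> None:
        if not (0 < self.identity_min <= 1 and 0 < self.coverage_min <= 1):
            raise ValueError("identity_min/coverage_min must lie in (0, 1]")
        if not (0 <= self.priming_a_frac <= 1):
            raise ValueError("priming_a_frac must lie in [0, 1]")
        if self.length_min < 1 or self.priming_window < 1 or self.synteny_pad < 0:
            raise ValueError("window/length parameters must be positive")
        if self.evalue_strict > self.evalue_loose:
            raise ValueError("evalue_strict must not exceed evalue_loose")
        if self.n_shuffles < 30:
            raise ValueError("n_shuffles must be >= 30")

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        cfg = cls(**data)
        cfg.validate()
        return cfg


@dataclass
class Dataset:
    """In-memory view of a dataset directory (forge layout)."""

    species_a: str
    genome_a: object
    genes_a: list
    transcripts: list
    partners: dict  # tag -> {"genome", "genes", "synteny"}
    cancer: object
    truth: Optional[dict] = None

    @classmethod
    def load(cls, path: str | Path) -> "Dataset":
        path = Path(path)
        meta_file = path / "forge_config.json"
        if not meta_file.exists():
            raise FileNotFoundError(f"{meta_file}: dataset metadata not found")
        meta = json.loads(meta_file.read_text())
        tag_a = meta["species_a"]
        genome_a = lio.read_genome_fasta(path / f"genome_{tag_a}.fasta", tag_a)
        genes_a = lio.read_annotation(path / f"genes_{tag_a}.gff3", "gff3")
        transcripts = lio.read_transcripts_fasta(path / "transcripts.fasta", tag_a)
        partners = {}
        for tag in sorted(meta["partners"]):
            syn_path = path / f"synteny_{tag_a}{tag}.tsv"
            if not syn_path.exists():
                raise FileNotFoundError(f"synteny map missing: {syn_path}")
            partners[tag] = {
                "genome": lio.read_genome_fasta(path / f"genome_{tag}.fasta", tag),
                "genes": lio.read_annotation(path / f"genes_{tag}.gff3", "gff3"),
                "synteny": lio.read_synteny_map(syn_path),
            }
        cancer_path = path / "cancer_genes.tsv"
        cancer = lio.read_cancer_genes(cancer_path) if cancer_path.exists() else None
        truth_path = path / "ground_truth.json"
        truth = json.loads(truth_path.read_text()) if truth_path.exists() else None
        return cls(tag_a, genome_a, genes_a, transcripts, partners, cancer, truth)


def _candidate_seed(seed: int, name: str) -> int:
    return (seed * 2654435761 + zlib.crc32(name.encode())) & 0x7FFFFFFF


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def _log(lines: list[str], msg: str) -> None:
    lines.append(msg)


# ---------------------------------------------------------------------------
# Stages


def stage_discover(cfg: PipelineConfig, data: Dataset, bundle: Path, log: list[str]) -> list[LncRNACandidate]:
    index = KmerIndex(data.genome_a)
    candidates = []
    n_mapped = 0
    for t in sorted(data.transcripts, key=lambda x: x.transcript_id):
        try:
            m = map_transcript(
                t,
                data.genome_a,
                index=index,
                min_identity=cfg.identity_min,
                min_coverage=cfg.coverage_min,
            )
        except Exception as exc:  # pragma: no cover - defensive
            raise PipelineError("map", t.transcript_id, str(exc))
        if m is None:
            continue
        n_mapped += 1
        if not gate_lncrna(m, t, data.genes_a, length_min=cfg.length_min, slop_nt=cfg.gate_slop_nt):
            continue
        origin, host = classify_origin(m, data.genes_a, proximity_nt=cfg.proximity_nt)
        cand = LncRNACandidate(
            transcript_id=t.transcript_id,
            mapping=m,
            origin_class=origin,
            host_gene_id=host,
            exon_count=m.exon_count,
        )
        cand.antisense_target = detect_antisense_utr(cand, data.genes_a)
        cand.priming_flag = internal_priming_filter(
            m,
            data.genome_a,
            window=cfg.priming_window,
            a_frac=cfg.priming_a_frac,
            a_run=cfg.priming_a_run,
        )
        candidates.append(cand)
    _log(log, f"discover: {len(data.transcripts)} transcripts in, {n_mapped} mapped, "
              f"{len(candidates)} candidates out")
    lio.write_candidate_report(candidates, bundle / "candidates.tsv")
    return candidates


def _transcript_by_id(data: Dataset) -> dict:
    return {t.transcript_id: t for t in data.transcripts}


def stage_orthology(cfg: PipelineConfig, data: Dataset, bundle: Path, log: list[str]) -> dict:
    candidates = lio.read_candidate_report(bundle / "candidates.json")
    seqs = _transcript_by_id(data)
    hits: dict[str, dict[str, OrthologHit]] = {}
    rows = []
    for cand in candidates:
        m = cand.mapping
        src = GenomeInterval(m.chrom, m.start, m.end, m.strand)
        per = {}
        for tag, part in data.partners.items():
            hit = find_ortholog(
                cand.transcript_id,
                seqs[cand.transcript_id].sequence,
                src,
                part["genome"],
                part["synteny"],
                pad=cfg.synteny_pad,
                evalue_strict=cfg.evalue_strict,
                evalue_loose=cfg.evalue_loose,
            )
            per[tag] = hit
            rows.append(
                {
                    "candidate_id": cand.transcript_id,
                    "species": tag,
                    "syntenic": hit.syntenic,
                    "score": hit.hit.score if hit.hit else 0,
                    "identity": round(hit.hit.identity, 1) if hit.hit else 0.0,
                    "evalue": hit.hit.evalue if hit.hit else "",
                    "homologous_at_1e6": hit.homologous_at_1e6,
                    "homologous_at_1e2": hit.homologous_at_1e2,
                    "target": _iv_str(hit.target_interval),
                }
            )
        hits[cand.transcript_id] = per
        cand.preservation_code = preservation_profile(data.species_a, per)
    _write_tsv(pd.DataFrame(rows), bundle / "orthologs.tsv")
    payload = {
        cid: {
            tag: {
                "syntenic": h.syntenic,
                "homologous_at_1e6": h.homologous_at_1e6,
                "homologous_at_1e2": h.homologous_at_1e2,
                "score": h.hit.score if h.hit else 0,
                "identity": h.hit.identity if h.hit else 0.0,
                "evalue": h.hit.evalue if h.hit else None,
                "target": (
                    [h.target_interval.chrom, h.target_interval.start,
                     h.target_interval.end, h.target_interval.strand]
                    if h.target_interval
                    else None
                ),
            }
            for tag, h in per.items()
        }
        for cid, per in hits.items()
    }
    with open(bundle / "orthologs.json", "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")
    lio.write_candidate_report(candidates, bundle / "candidates.tsv")
    n_hom = sum(1 for per in hits.values() if any(h.homologous_at_1e2 for h in per.values()))
    _log(log, f"orthology: {len(candidates)} candidates, {n_hom} with homologous ortholog")
    return hits


def _iv_str(ivl: Optional[GenomeInterval]) -> str:
    return f"{ivl.chrom}:{ivl.start}-{ivl.end}({ivl.strand})" if ivl else ""


def _load_ortholog_hits(bundle: Path) -> dict:
    with open(bundle / "orthologs.json") as fh:
        raw = json.load(fh)
    out: dict[str, dict[str, OrthologHit]] = {}
    from lncsieve.alignment import AlignmentResult

    for cid, per in raw.items():
        out[cid] = {}
        for tag, d in per.items():
            hit = None
            if d["evalue"] is not None:
                hit = AlignmentResult(
                    score=d["score"], identity=d["identity"], query_start=0,
                    query_end=0, target_start=0, target_end=0,
                    evalue=d["evalue"], aligned_length=0,
                )
            target = None
            if d["target"]:
                target = GenomeInterval(*d["target"][:3], d["target"][3])
            out[cid][tag] = OrthologHit(
                candidate_id=cid,
                species_tag=tag,
                hit=hit,
                syntenic=d["syntenic"],
                homologous_at_1e6=d["homologous_at_1e6"],
                homologous_at_1e2=d["homologous_at_1e2"],
                target_interval=target,
            )
    return out


def _primary_partner(data: Dataset) -> str:
    return sorted(data.partners)[0]


def stage_selection(cfg: PipelineConfig, data: Dataset, bundle: Path, log: list[str]) -> None:
    candidates = lio.read_candidate_report(bundle / "candidates.json")
    hits = _load_ortholog_hits(bundle)
    seqs = _transcript_by_id(data)
    tag = _primary_partner(data)
    part = data.partners[tag]
    genes_a = {g.gene_id: g for g in data.genes_a}
    genes_b = {g.gene_id: g for g in part["genes"]}

    flank_rows = []
    lnc_pairs = []
    parent_pairs = []
    for cand in candidates:
        hit = hits.get(cand.transcript_id, {}).get(tag)
        if hit is None or not hit.homologous_at_1e2 or hit.target_interval is None:
            continue
        m = cand.mapping
        src = GenomeInterval(m.chrom, m.start, m.end, m.strand)
        try:
            fc = flank_contrast(
                cand.transcript_id, src, hit, data.genome_a, part["genome"],
                part["synteny"], pad=cfg.synteny_pad, evalue_max=cfg.evalue_loose,
            )
        except ValueError as exc:
            raise PipelineError("flank_contrast", cand.transcript_id, str(exc))
        cand.lnc_identity = fc.lnc_identity
        cand.flank_identity = fc.flank_identity
        flank_rows.append(
            {
                "candidate_id": fc.candidate_id,
                "lnc_identity": round(fc.lnc_identity, 1),
                "flank_identity": (
                    "not conserved" if fc.flank_identity is None else round(fc.flank_identity, 1)
                ),
                "rendering": lio.render_identity(fc.lnc_identity, fc.flank_identity),
                "truncated": fc.truncated,
            }
        )
        lnc_pairs.append(
            (
                cand.transcript_id,
                seqs[cand.transcript_id].sequence,
                part["genome"].fetch(hit.target_interval),
            )
        )
        host = cand.host_gene_id
        if host and host in genes_b:
            cds_a = _cds_sequence(data.genome_a, genes_a[host])
            cds_b = _cds_sequence(part["genome"], genes_b[host])
            if len(cds_a) == len(cds_b):
                parent_pairs.append((cand.transcript_id, cds_a, cds_b))
    _write_tsv(pd.DataFrame(flank_rows), bundle / "flank_contrast.tsv")
    rows = kaks_contrast(lnc_pairs, parent_pairs, evalue_max=cfg.evalue_loose)
    out_rows = []
    for r in rows:
        for role, key in (("lncRNA", "result_lnc"), ("parent", "result_parent")):
            res = r.get(key)
            if res is None:
                out_rows.append({"candidate_id": r["candidate_id"], "role": role,
                                 "ka": "", "ks": "", "ratio": "",
                                 "s_sites": "", "n_sites": "", "sd": "", "nd": "",
                                 "band": r.get("band_lnc" if role == "lncRNA" else "band_parent", "")})
            else:
                out_rows.append({"candidate_id": r["candidate_id"], "role": role,
                                 "ka": res.ka, "ks": res.ks,
                                 "ratio": "" if res.ratio is None else res.ratio,
                                 "s_sites": res.s_sites, "n_sites": res.n_sites,
                                 "sd": res.sd, "nd": res.nd,
                                 "band": r.get("band_lnc" if role == "lncRNA" else "band_parent", "")})
    _write_tsv(pd.DataFrame(out_rows), bundle / "kaks.tsv")
    lio.write_candidate_report(candidates, bundle / "candidates.tsv")
    _log(log, f"selection: {len(flank_rows)} conserved pairs contrasted, "
              f"{len(parent_pairs)} parent CDS pairs")


def _cds_sequence(genome, gene) -> str:
    """CDS in transcription order with the terminal stop codon removed."""
    from lncsieve.models import revcomp

    fwd = "".join(
        genome.chrom_sequences[gene.span.chrom][c.start : c.end]
        for c in sorted(gene.cds, key=lambda x: x.start)
    )
    seq = revcomp(fwd) if gene.strand == "-" else fwd
    return seq[:-3] if len(seq) >= 6 else seq


def stage_structure(cfg: PipelineConfig, data: Dataset, bundle: Path, log: list[str]) -> None:
    candidates = lio.read_candidate_report(bundle / "candidates.json")
    hits = _load_ortholog_hits(bundle)
    seqs = _transcript_by_id(data)
    tag = _primary_partner(data)
    part = data.partners[tag]
    rows = []
    for cand in candidates:
        hit = hits.get(cand.transcript_id, {}).get(tag)
        if hit is None or not hit.homologous_at_1e2 or hit.target_interval is None:
            continue
        rep = evaluate_pair(
            cand.transcript_id,
            seqs[cand.transcript_id].sequence,
            part["genome"].fetch(hit.target_interval),
            n_shuffles=cfg.n_shuffles,
            seed=_candidate_seed(cfg.seed, cand.transcript_id),
            z_min=cfg.z_min,
            sci_min=cfg.sci_min,
        )
        cand.structure_flag = rep.structured
        rows.append(
            {
                "candidate_id": rep.candidate_id,
                "fold_score": rep.fold_score,
                "zscore": round(rep.zscore, 3),
                "sci": round(rep.sci, 4),
                "structured": rep.structured,
            }
        )
    _write_tsv(pd.DataFrame(rows), bundle / "structure.tsv")
    lio.write_candidate_report(candidates, bundle / "candidates.tsv")
    _log(log, f"structure: {len(rows)} pairs screened, "
              f"{sum(1 for r in rows if r['structured'])} structured")


def stage_enrich(cfg: PipelineConfig, data: Dataset, bundle: Path, log: list[str]) -> dict:
    candidates = lio.read_candidate_report(bundle / "candidates.json")
    hosts = sorted({c.host_gene_id for c in candidates if c.host_gene_id})
    all_genes = sorted({g.gene_id for g in data.genes_a})
    report: dict = {"hosts": hosts, "n_hosts": len(hosts)}
    if data.cancer is not None and hosts:
        table = build_table(hosts, all_genes, data.cancer)
        report.update(enrichment_report(table))
    with open(bundle / "enrichment.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
        fh.write("\n")
    _log(log, f"enrich: {len(hosts)} host genes of {len(all_genes)}")
    return report


def stage_summary(cfg: PipelineConfig, data: Dataset, bundle: Path, log: list[str]) -> dict:
    candidates = lio.read_candidate_report(bundle / "candidates.json")
    hits = _load_ortholog_hits(bundle)
    tag = _primary_partner(data)
    tallies = classify_conservation(
        candidates, {cid: per.get(tag) for cid, per in hits.items()}
    )
    exons = exon_summary(candidates)
    enrichment = {}
    enr_path = bundle / "enrichment.json"
    if enr_path.exists():
        enrichment = json.loads(enr_path.read_text())
    summary = {
        "conservation": tallies,
        "exons": exons,
        "enrichment": enrichment,
        "origin_classes": _origin_counts(candidates),
        "priming_flagged": sum(1 for c in candidates if c.priming_flag),
        "antisense_utr": sum(1 for c in candidates if c.antisense_target),
        "structured": sum(1 for c in candidates if c.structure_flag),
        "preservation_codes": sorted(
            {c.transcript_id: c.preservation_code for c in candidates}.items()
        ),
    }
    with open(bundle / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
        fh.write("\n")
    with open(bundle / "summary.txt", "w") as fh:
        fh.write(render_summary(summary))
    return summary


def _origin_counts(candidates) -> dict:
    out: dict[str, int] = {}
    for c in candidates:
        out[c.origin_class] = out.get(c.origin_class, 0) + 1
    return dict(sorted(out.items()))


def render_summary(summary: dict) -> str:
    t = summary["conservation"]
    e = summary["exons"]
    lines = [
        "lncRNA discovery summary",
        "========================",
        f"Candidates: {t['total']}",
        f"  With significant sequence homology:    {t['with_significant_homology']}",
        f"  Without significant sequence homology: {t['without_significant_homology']}",
        f"  Protein-coding region: {t['protein_coding_region']}",
        f"  Non-protein-coding region: {t['non_protein_coding_region']}",
        f"  Spliced: {t['spliced']} / Non spliced: {t['non_spliced']}",
        f"Single-exon: {e['single_exon']} of {e['total']} ({e['percent_single_exon']}%)"
        if e["total"]
        else "Single-exon: n/a",
        f"Origin classes: {summary['origin_classes']}",
        f"Internal-priming flagged: {summary['priming_flagged']}",
        f"Antisense-UTR configurations: {summary['antisense_utr']}",
        f"Structured (z & SCI): {summary['structured']}",
    ]
    enr = summary.get("enrichment") or {}
    if "chi2_yates_p" in enr:
        lines += [
            f"Cancer enrichment: {enr['k']}/{enr['n']} host vs {enr['K']}/{enr['N']} background "
            f"({enr['host_cancer_percent']}% vs {enr['background_cancer_percent']}%)",
            f"  chi-square (Yates) P = {enr['chi2_yates_p']:.3g}; "
            f"hypergeometric P(X=k) = {enr['hypergeom_point_p']:.3g}; "
            f"P(X>=k) = {enr['hypergeom_tail_p']:.3g}",
        ]
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Orchestration


def run_pipeline(
    dataset_dir: str | Path,
    out_dir: str | Path,
    config: Optional[PipelineConfig] = None,
) -> dict:
    """Run every stage over a dataset directory; returns the summary dict."""
    cfg = config or PipelineConfig()
    cfg.validate()
    data = Dataset.load(dataset_dir)
    bundle = Path(out_dir)
    bundle.mkdir(parents=True, exist_ok=True)
    log: list[str] = [
        "lncsieve run log",
        f"dataset: {Path(dataset_dir).name}",
        f"config: {json.dumps(asdict(cfg), sort_keys=True)}",
    ]
    stage_discover(cfg, data, bundle, log)
    stage_orthology(cfg, data, bundle, log)
    stage_selection(cfg, data, bundle, log)
    stage_structure(cfg, data, bundle, log)
    stage_enrich(cfg, data, bundle, log)
    summary = stage_summary(cfg, data, bundle, log)
    (bundle / "run_log.txt").write_text("\n".join(log) + "\n")
    return summary


def summarize(bundle_dir: str | Path) -> str:
    """Render the text summary from an existing report bundle."""
    with open(Path(bundle_dir) / "summary.json") as fh:
        return render_summary(json.load(fh))
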