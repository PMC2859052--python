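"""Synthetic paired-genome forge with planted ground truth.

Two (or more) toy "species" are generated: genome A is the home species (tag
"M" by default, the reference whose transcripts are mined) and each partner
genome is derived from A by controlled mutation:

* protein-coding gene pairs: codon-aware substitution of the CDS toward a
  target Ka/Ks (synonymous and nonsynonymous changes drawn independently at
  per-site rates derived from the target), UTRs and introns at an
  independent neutral rate; the realized Ka/Ks of every pair is recorded in
  the ground truth from the introduced-change counts;
* planted lncRNAs of each origin class (UTR-only, intron-only, mixed,
  near-gene, intergenic, optionally spliced and antisense-UTR), copied
  verbatim into the transcript set and mutated in the partner genome to a
  controlled identity -- or replaced by random sequence for the
  "syntenic but not homologous" class;
* flanking buffers of intergenic lncRNAs with controlled conservation
  (mutated at a heavier rate than the lncRNA, or randomized);
* internal-priming decoys: the 50-nt window downstream of selected lncRNAs
  is rewritten A-rich; windows of all other planted lncRNAs are guaranteed
  negative for the priming filter, so decoy recovery is exact by
  construction;
* a cancer-gene list with an elevated annotation rate among lncRNA hosts.

Every feature draws from its own deterministic RNG stream (seeded from the
forge seed and the feature id), so adding features does not perturb earlier
ones, and a fixed seed yields byte-identical output directories.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from math import exp
from pathlib import Path
from typing import Optional

import numpy as np

from lncsieve import io as lio
from lncsieve.models import (
    CancerGeneSet,
    GeneModel,
    GenomeInterval,
    GenomeRecord,
    SyntenyBlock,
    TranscriptRecord,
    revcomp,
)
from lncsieve.selection import _CODON_TABLE, _codon_sites, _jukes_cantor

BASES = "ACGT"
TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}

ORIGIN_CLASSES = ("utr_only", "intron_only", "mixed", "near_gene", "intergenic")


class ForgeError(RuntimeError):
    pass


@dataclass
class ForgeConfig:
    """Study conditions for the synthetic dataset.

    Defaults give a two-species comparison at mammal-like divergence on a
    minutes-scale problem: 2 chromosomes x 100 kb, 20 protein-coding genes,
    13 planted lncRNAs plus one spliced and one antisense plant.
    """

    seed: int = 0
    species_a: str = "M"
    partners: dict = field(default_factory=lambda: {"H": 1.0})  # tag -> rate scale
    n_chromosomes: int = 2
    chrom_length: int = 100_000
    gc_content: float = 0.42
    n_genes: int = 20
    n_lnc_per_class: dict = field(
        default_factory=lambda: {
            "utr_only": 3,
            "intron_only": 3,
            "mixed": 2,
            "near_gene": 2,
            "intergenic": 3,
        }
    )
    n_antisense: int = 1
    n_spliced_intergenic: int = 1
    lnc_identity_range: tuple = (0.80, 0.92)
    conserved_fraction: float = 0.75
    flank_conserved_fraction: float = 0.5
    flank_mutation_rate: float = 0.30
    neutral_rate: float = 0.12
    indel_rate: float = 5e-4
    priming_fraction: float = 0.2
    target_kaks: tuple = (0.1, 0.2, 0.3)
    ks_target: float = 0.25
    mrna_fraction: float = 0.5
    cancer_host_fraction: float = 0.5
    cancer_background_fraction: float = 0.1

    def validate(self) -> None:
        fracs = [
            self.gc_content,
            self.conserved_fraction,
            self.flank_conserved_fraction,
            self.priming_fraction,
            self.mrna_fraction,
            self.cancer_host_fraction,
            self.cancer_background_fraction,
            *self.lnc_identity_range,
        ]
        if any(not (0.0 <= f <= 1.0) for f in fracs):
            raise ForgeError("all fractions must lie in [0, 1]")
        if any(k < 0 for k in self.target_kaks) or self.ks_target < 0:
            raise ForgeError("target Ka/Ks values must be non-negative")
        if self.n_genes < 0 or self.n_chromosomes < 1:
            raise ForgeError("invalid gene/chromosome counts")


# ---------------------------------------------------------------------------
# RNG streams


def _feature_rng(seed: int, name: str) -> np.random.Generator:
    key = zlib.crc32(name.encode()) & 0x7FFFFFFF
    return np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, key]))


def _random_seq(rng: np.random.Generator, n: int, gc: float = 0.42) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(np.array(list(BASES))[rng.choice(4, size=n, p=p)])


def _mutate_base(b: str, rng: np.random.Generator) -> str:
    """Substitute with 2:1 transition:transversion bias."""
    if rng.random() < 0.5:
        return TRANSITION[b]
    opts = [x for x in BASES if x != b and x != TRANSITION[b]]
    return opts[int(rng.integers(2))]


def _mutate_seq(seq: str, rate: float, rng: np.random.Generator) -> str:
    out = list(seq)
    for i in range(len(out)):
        if out[i] in TRANSITION and rng.random() < rate:
            out[i] = _mutate_base(out[i], rng)
    return "".join(out)


# ---------------------------------------------------------------------------
# Coding sequence forging


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    """ATG + (n_codons-2) random non-stop codons + stop."""
    codons = ["ATG"]
    sense = [c for c, aa in _CODON_TABLE.items() if aa != "*"]
    for _ in range(n_codons - 2):
        codons.append(sense[int(rng.integers(len(sense)))])
    stops = sorted(c for c, aa in _CODON_TABLE.items() if aa == "*")
    codons.append(stops[int(rng.integers(len(stops)))])
    return "".join(codons)


def mutate_cds(
    cds: str,
    target_kaks: float,
    ks_target: float,
    rng: np.random.Generator,
) -> tuple[str, dict]:
    """Codon-aware mutation of a CDS toward a target Ka/Ks.

    Per codon, a synonymous change is applied with probability pS*s_i and a
    nonsynonymous (non-stop) change with probability pN*n_i, where pS/pN are
    the raw proportions whose Jukes-Cantor corrections equal ks_target and
    ks_target*target_kaks. Start and stop codons are left synonymous-only.
    Returns the mutated CDS and the realized substitution accounting
    (including the realized Ka/Ks from the introduced-change counts).
    """
    if target_kaks < 0:
        raise ForgeError("target_kaks must be >= 0")
    pS = 0.75 * (1.0 - exp(-4.0 * ks_target / 3.0))
    pN = 0.75 * (1.0 - exp(-4.0 * ks_target * target_kaks / 3.0))
    out = []
    sd = nd = 0
    s_sites = n_sites = 0.0
    for i in range(0, len(cds), 3):
        codon = cds[i : i + 3]
        aa = _CODON_TABLE[codon]
        si, ni = _codon_sites(codon)
        s_sites += si
        n_sites += ni
        c = codon
        # at most one substitution per codon, so the introduced-change
        # accounting matches endpoint pathway counting exactly
        first_or_last = i == 0 or i == len(cds) - 3
        q_s = min(1.0, pS * si)
        q_n = 0.0 if (aa == "*" or first_or_last) else min(1.0, pN * ni)
        total = q_s + q_n
        if total > 1.0:
            q_s, q_n = q_s / total, q_n / total
        u = rng.random()
        if u < q_s:
            opts = _single_nt_neighbors(c, synonymous=True)
            if opts:
                c = opts[int(rng.integers(len(opts)))]
                sd += 1
        elif u < q_s + q_n:
            opts = _single_nt_neighbors(c, synonymous=False)
            if opts:
                c = opts[int(rng.integers(len(opts)))]
                nd += 1
        out.append(c)
    realized_ks = _jukes_cantor(sd / s_sites) if s_sites else 0.0
    realized_ka = _jukes_cantor(nd / n_sites) if n_sites else 0.0
    realized = None
    if realized_ks not in (None, 0.0) and realized_ka is not None:
        realized = realized_ka / realized_ks
    return "".join(out), {
        "sd": sd,
        "nd": nd,
        "s_sites": s_sites,
        "n_sites": n_sites,
        "realized_ka": realized_ka,
        "realized_ks": realized_ks,
        "realized_kaks": realized,
    }


def _single_nt_neighbors(codon: str, synonymous: bool) -> list[str]:
    aa = _CODON_TABLE[codon]
    out = []
    for pos in range(3):
        for alt in BASES:
            if alt == codon[pos]:
                continue
            mut = codon[:pos] + alt + codon[pos + 1 :]
            maa = _CODON_TABLE[mut]
            if maa == "*" and aa != "*":
                continue
            if (maa == aa) == synonymous:
                out.append(mut)
    return out


def make_codon_pair(
    n_codons: int,
    target_kaks: float,
    ks_target: float = 0.25,
    rng: Optional[np.random.Generator] = None,
    realized_range: Optional[tuple] = None,
) -> tuple[str, str, dict]:
    """A coding ortholog pair (without start/stop trimming concerns).

    With realized_range=(lo, hi) the draw is repeated until the realized
    Ka/Ks lands inside the range, certifying the pair's selection label
    (finite-length sampling noise otherwise scatters the realized ratio
    around the target).
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    for _ in range(100):
        a = _random_cds(rng, n_codons + 2)
        b, realized = mutate_cds(a, target_kaks, ks_target, rng)
        if realized_range is None:
            break
        r = realized["realized_kaks"]
        if r is not None and realized_range[0] <= r <= realized_range[1]:
            break
    return a[3:-3], b[3:-3], realized


# ---------------------------------------------------------------------------
# Structure-test helpers


def make_hairpin(stem: int = 20, loop: int = 8, tail: int = 15,
                 rng: Optional[np.random.Generator] = None) -> str:
    """A sequence folding into one strong GC-rich hairpin."""
    rng = rng if rng is not None else np.random.default_rng(0)
    s = _random_seq(rng, stem, gc=0.7)
    return _random_seq(rng, tail) + s + _random_seq(rng, loop) + revcomp(s) + _random_seq(rng, tail)


def _quick_z(seq: str, rng: np.random.Generator) -> float:
    from lncsieve.structure import shuffle_zscore

    z, degenerate = shuffle_zscore(seq, n_shuffles=60, seed=int(rng.integers(2**31)))
    return 0.0 if degenerate else z


def make_hairpin_pair(
    stem: int = 20,
    loop: int = 8,
    tail: int = 15,
    n_compensatory: int = 4,
    rng: Optional[np.random.Generator] = None,
    min_z: float = 3.5,
) -> tuple[str, str]:
    """A hairpin and a partner with compensatory double substitutions.

    n_compensatory stem pairs are swapped to a different complementary pair
    (e.g. G:C -> A:T), preserving the pairing, plus light mutation of the
    unpaired tails/loop. The planted "structured" label is guaranteed: the
    stem is resampled until the stability z-score clears min_z, so a rare
    draw whose dinucleotide shuffles fold nearly as well is rejected.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    for _ in range(50):
        s = list(_random_seq(rng, stem, gc=0.7))
        t1 = _random_seq(rng, tail)
        lp = _random_seq(rng, loop)
        t2 = _random_seq(rng, tail)
        a = t1 + "".join(s) + lp + revcomp("".join(s)) + t2
        if _quick_z(a, rng) >= min_z:
            break
    s2 = list(s)
    pos = rng.choice(stem, size=min(n_compensatory, stem), replace=False)
    for p in pos:
        s2[p] = {"G": "A", "C": "T", "A": "G", "T": "C"}[s2[p]]
    b = (
        _mutate_seq(t1, 0.1, rng)
        + "".join(s2)
        + _mutate_seq(lp, 0.1, rng)
        + revcomp("".join(s2))
        + _mutate_seq(t2, 0.1, rng)
    )
    return a, b


def make_unstructured_pair(
    n: int = 100,
    rate: float = 0.1,
    rng: Optional[np.random.Generator] = None,
    max_z: float = 0.8,
) -> tuple[str, str]:
    """A conserved but structureless pair: random sequence plus light mutation.

    Random sequences occasionally contain genuine hairpins; the draw is
    rejected until the stability z-score falls below max_z, so the planted
    "unstructured" label holds by construction.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    for _ in range(50):
        a = _random_seq(rng, n)
        if _quick_z(a, rng) <= max_z:
            break
    return a, _mutate_seq(a, rate, rng)


# ---------------------------------------------------------------------------
# Enrichment-test helper


def forge_cancer_labels(
    n_genes: int,
    n_hosts: int,
    host_fraction: float,
    background_fraction: float,
    rng: Optional[np.random.Generator] = None,
) -> tuple[list[str], list[str], CancerGeneSet]:
    """Gene universe with elevated cancer-annotation rate among hosts."""
    rng = rng if rng is not None else np.random.default_rng(0)
    all_genes = [f"gene{i:05d}" for i in range(n_genes)]
    hosts = all_genes[:n_hosts]
    cancer = set()
    for g in all_genes:
        p = host_fraction if g in set(hosts) else background_fraction
        if rng.random() < p:
            cancer.add(g)
    return hosts, all_genes, CancerGeneSet(cancer, "forged cancer set")


# ---------------------------------------------------------------------------
# Priming decoys


def plant_priming_decoy(
    chrom_seq: str,
    end: int,
    strand: str,
    rng: np.random.Generator,
    window: int = 50,
) -> str:
    """Rewrite the 50-nt window downstream of a mapped 3' end to be A-rich.

    For '+' the window is [end, end+window) filled with ~85% A; for '-' the
    3' end is the interval start and the window upstream is filled with the
    reverse-complement pattern. Raises ForgeError at a chromosome end.
    """
    if strand == "+":
        lo, hi = end, end + window
    else:
        lo, hi = end - window, end
    if lo < 0 or hi > len(chrom_seq):
        raise ForgeError("no room for a priming decoy window at the chromosome end")
    tract = "".join("A" if rng.random() < 0.85 else _random_seq(rng, 1) for _ in range(window))
    if strand == "-":
        tract = revcomp(tract)
    return chrom_seq[:lo] + tract + chrom_seq[hi:]


def _window_is_primed(win: str, a_frac: float = 0.65, a_run: int = 8) -> bool:
    if not win:
        return False
    if win.count("A") / len(win) >= a_frac:
        return True
    run = 0
    for c in win:
        run = run + 1 if c == "A" else 0
        if run >= a_run:
            return True
    return False


# ---------------------------------------------------------------------------
# Layout bookkeeping


@dataclass
class _PlannedGene:
    gene_id: str
    chrom: str
    start: int
    strand: str
    # transcription-order layout (local coordinates)
    u5: int = 150
    intron1: int = 650
    cds1: int = 201
    intron2: int = 400
    cds2: int = 204
    u3: int = 450
    target_kaks: float = 0.2

    @property
    def length(self) -> int:
        return self.u5 + self.intron1 + self.cds1 + self.intron2 + self.cds2 + self.u3

    def local_features(self) -> dict:
        o = 0
        feats = {}
        for name, ln in (
            ("u5", self.u5),
            ("intron1", self.intron1),
            ("cds1", self.cds1),
            ("intron2", self.intron2),
            ("cds2", self.cds2),
            ("u3", self.u3),
        ):
            feats[name] = (o, o + ln)
            o += ln
        return feats

    def genomic(self, local: tuple[int, int]) -> tuple[int, int]:
        """Map a transcription-order local interval to genomic coordinates."""
        s, e = local
        if self.strand == "+":
            return self.start + s, self.start + e
        L = self.length
        return self.start + L - e, self.start + L - s


@dataclass
class _PlannedLnc:
    lnc_id: str
    origin_class: str
    chrom: str
    blocks: list[tuple[int, int]]  # genomic, sorted
    strand: str
    host_gene: Optional[str]
    conserved: bool
    target_identity: Optional[float]
    priming_decoy: bool = False
    antisense: bool = False
    flank_status: Optional[str] = None  # conserved | not_conserved | None

    @property
    def start(self) -> int:
        return self.blocks[0][0]

    @property
    def end(self) -> int:
        return self.blocks[-1][1]

    @property
    def spliced(self) -> bool:
        return len(self.blocks) > 1


# treatment codes for the partner-genome painter
_T_FILLER = 0
_T_NEUTRAL = 1
_T_CDS = 2
_T_LNC = 3
_T_FLANK_CONS = 4
_T_RANDOMIZE = 5


# ---------------------------------------------------------------------------
# The forge


@dataclass
class ForgeResult:
    config: ForgeConfig
    genome_a: GenomeRecord
    genes_a: list
    transcripts: list
    partners: dict  # tag -> {"genome", "genes", "synteny"}
    cancer: CancerGeneSet
    truth: dict

    def emit(self, outdir: str | Path) -> Path:
        """Write the dataset directory in the formats the readers consume."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        lio.write_genome_fasta(self.genome_a, out / f"genome_{self.config.species_a}.fasta")
        lio.write_gff3(self.genes_a, out / f"genes_{self.config.species_a}.gff3")
        lio.write_transcripts_fasta(self.transcripts, out / "transcripts.fasta")
        for tag, part in self.partners.items():
            lio.write_genome_fasta(part["genome"], out / f"genome_{tag}.fasta")
            lio.write_gff3(part["genes"], out / f"genes_{tag}.gff3")
            lio.write_synteny_map(part["synteny"], out / f"synteny_{self.config.species_a}{tag}.tsv")
        lio.write_cancer_genes(self.cancer, out / "cancer_genes.tsv")
        with open(out / "ground_truth.json", "w") as fh:
            json.dump(self.truth, fh, indent=1, sort_keys=True)
            fh.write("\n")
        with open(out / "forge_config.json", "w") as fh:
            json.dump(asdict(self.config), fh, indent=1, sort_keys=True)
            fh.write("\n")
        return out


class Forge:
    """Build a full synthetic dataset from a ForgeConfig."""

    LNC_LEN = {"utr_only": 280, "intron_only": 300, "mixed": 300, "near_gene": 300, "intergenic": 300}

    def __init__(self, config: ForgeConfig):
        config.validate()
        self.cfg = config
        self.chroms = [f"chr{i + 1}" for i in range(config.n_chromosomes)]

    def _rng(self, name: str) -> np.random.Generator:
        return _feature_rng(self.cfg.seed, name)

    # -- layout ------------------------------------------------------------

    def _plan(self) -> tuple[list[_PlannedGene], list[_PlannedLnc]]:
        cfg = self.cfg
        cursors = {c: 2500 for c in self.chroms}
        genes: list[_PlannedGene] = []
        kaks_cycle = list(cfg.target_kaks) or [0.2]
        for gi in range(cfg.n_genes):
            chrom = self.chroms[gi % len(self.chroms)]
            g = _PlannedGene(
                gene_id=f"gene{gi:03d}",
                chrom=chrom,
                start=cursors[chrom],
                strand="+" if gi % 3 else "-",
                target_kaks=kaks_cycle[gi % len(kaks_cycle)],
            )
            genes.append(g)
            cursors[chrom] += g.length + 3500
        # gene-linked lncRNA assignments, one per gene
        linked: list[tuple[str, bool]] = []
        for cls in ("utr_only", "intron_only", "mixed", "near_gene"):
            linked += [(cls, False)] * cfg.n_lnc_per_class.get(cls, 0)
        linked += [("utr_only", True)] * cfg.n_antisense
        if len(linked) > len(genes):
            raise ForgeError("not enough genes to host the gene-linked lncRNAs")
        lncs: list[_PlannedLnc] = []
        counter: dict[str, int] = {}
        for (cls, antisense), g in zip(linked, genes):
            idx = counter.get(cls + ("_as" if antisense else ""), 0)
            counter[cls + ("_as" if antisense else "")] = idx + 1
            suffix = f"as{idx:02d}" if antisense else f"{idx:02d}"
            lnc_id = f"lnc_{cls}_{suffix}"
            feats = g.local_features()
            L = self.LNC_LEN[cls]
            if cls == "utr_only":
                s, _ = feats["u3"]
                block = g.genomic((s + 60, s + 60 + L))
                strand = _flip(g.strand) if antisense else g.strand
                blocks = [block]
            elif cls == "intron_only":
                s, _ = feats["intron1"]
                blocks = [g.genomic((s + 80, s + 80 + L))]
                strand = g.strand
            elif cls == "mixed":
                gene_s, gene_e = g.start, g.start + g.length
                if g.strand == "+":
                    blocks = [(gene_e - L // 2, gene_e + L // 2)]
                else:
                    blocks = [(gene_s - L // 2, gene_s + L // 2)]
                strand = g.strand
            else:  # near_gene
                d = 150 + int(self._rng(f"near/{lnc_id}").integers(550))
                gene_e = g.start + g.length
                blocks = [(gene_e + d, gene_e + d + L)]
                strand = "+" if idx % 2 == 0 else "-"
            lncs.append(self._finish_lnc(lnc_id, cls, g.chrom, blocks, strand, g.gene_id))
        # intergenic lncRNAs (plus spliced variants) at the chromosome tails
        n_int = cfg.n_lnc_per_class.get("intergenic", 0)
        for k in range(n_int + cfg.n_spliced_intergenic):
            spliced = k >= n_int
            lnc_id = f"lnc_intergenic_{'sp' if spliced else ''}{k:02d}"
            chrom = self.chroms[k % len(self.chroms)]
            cur = cursors[chrom] + 1500
            if spliced:
                blocks = [(cur + 340, cur + 500), (cur + 750, cur + 930)]
                span = 930 - 340 + 2 * 340
                cursors[chrom] = cur + 930 + 340 + 500
            else:
                L = self.LNC_LEN["intergenic"]
                blocks = [(cur + L, cur + 2 * L)]
                cursors[chrom] = cur + 3 * L + 500
            lncs.append(
                self._finish_lnc(lnc_id, "intergenic", chrom, blocks, "+" if k % 2 else "-", None)
            )
        for chrom, cur in cursors.items():
            if cur + 2000 > self.cfg.chrom_length:
                raise ForgeError(
                    f"{chrom}: layout needs {cur + 2000} nt but chrom_length is {self.cfg.chrom_length}"
                )
        return genes, lncs

    def _finish_lnc(self, lnc_id, cls, chrom, blocks, strand, host) -> _PlannedLnc:
        cfg = self.cfg
        rng = self._rng(f"lncmeta/{lnc_id}")
        conserved = bool(rng.random() < cfg.conserved_fraction)
        lo, hi = cfg.lnc_identity_range
        identity = float(lo + (hi - lo) * rng.random()) if conserved else None
        decoy = bool(rng.random() < cfg.priming_fraction)
        flank_status = None
        if cls == "intergenic" and conserved:
            flank_status = (
                "conserved" if rng.random() < cfg.flank_conserved_fraction else "not_conserved"
            )
        return _PlannedLnc(
            lnc_id=lnc_id,
            origin_class=cls,
            chrom=chrom,
            blocks=blocks,
            strand=strand,
            host_gene=host,
            conserved=conserved,
            target_identity=identity,
            priming_decoy=decoy,
            antisense="as" in lnc_id,
            flank_status=flank_status,
        )

    # -- genome A ----------------------------------------------------------

    def _assemble_a(self, genes: list[_PlannedGene]) -> tuple[dict, dict]:
        cfg = self.cfg
        arrs = {}
        cds_store = {}
        for chrom in self.chroms:
            arrs[chrom] = list(
                _random_seq(self._rng(f"genomeA/{chrom}"), cfg.chrom_length, cfg.gc_content)
            )
        for g in genes:
            rng = self._rng(f"gene/{g.gene_id}")
            n_codons = (g.cds1 + g.cds2) // 3
            cds = _random_cds(rng, n_codons)
            region = (
                _random_seq(rng, g.u5, cfg.gc_content)
                + _random_seq(rng, g.intron1, cfg.gc_content)
                + cds[: g.cds1]
                + _random_seq(rng, g.intron2, cfg.gc_content)
                + cds[g.cds1 :]
                + _random_seq(rng, g.u3, cfg.gc_content)
            )
            if g.strand == "-":
                region = revcomp(region)
            arrs[g.chrom][g.start : g.start + g.length] = list(region)
            cds_store[g.gene_id] = cds
        return arrs, cds_store

    def _apply_priming(self, arrs: dict, lncs: list[_PlannedLnc]) -> None:
        """Plant decoy windows; guarantee non-decoy windows are filter-negative."""
        for lnc in lncs:
            chrom_seq = "".join(arrs[lnc.chrom])
            if lnc.strand == "+":
                lo, hi = lnc.end, min(lnc.end + 50, len(chrom_seq))
            else:
                lo, hi = max(0, lnc.start - 50), lnc.start
            if lnc.priming_decoy:
                edited = plant_priming_decoy(
                    chrom_seq,
                    lnc.end if lnc.strand == "+" else lnc.start,
                    lnc.strand,
                    self._rng(f"decoy/{lnc.lnc_id}"),
                )
                arrs[lnc.chrom] = list(edited)
            else:
                rng = self._rng(f"primingfix/{lnc.lnc_id}")
                win = chrom_seq[lo:hi]
                oriented = revcomp(win) if lnc.strand == "-" else win
                while _window_is_primed(oriented):
                    win = _random_seq(rng, hi - lo, 0.5)
                    oriented = revcomp(win) if lnc.strand == "-" else win
                arrs[lnc.chrom][lo:hi] = list(win)

    def _gene_model(self, g: _PlannedGene) -> GeneModel:
        feats = g.local_features()
        mk = lambda local, : GenomeInterval(g.chrom, *g.genomic(local), g.strand)
        u5 = mk(feats["u5"])
        cds1 = mk(feats["cds1"])
        cds2 = mk(feats["cds2"])
        u3 = mk(feats["u3"])
        # cds2 and u3 are contiguous: one exon holding both
        ex3_pairs = sorted([cds2.pair, u3.pair])
        ex3 = GenomeInterval(g.chrom, ex3_pairs[0][0], ex3_pairs[1][1], g.strand)
        exons = sorted([u5, cds1, ex3], key=lambda x: x.start)
        model = GeneModel(
            gene_id=g.gene_id,
            transcript_id=f"mrna_{g.gene_id}",
            span=GenomeInterval(g.chrom, g.start, g.start + g.length, g.strand),
            exons=exons,
            cds=sorted([cds1, cds2], key=lambda x: x.start),
            utr5=[u5],
            utr3=[u3],
        )
        model.validate()
        return model

    # -- partner genomes ----------------------------------------------------

    def _paint(self, genes, lncs, gene_models) -> dict:
        L = self.cfg.chrom_length
        paint = {c: np.zeros(L, dtype=np.uint8) for c in self.chroms}
        owner = {c: np.full(L, -1, dtype=np.int32) for c in self.chroms}
        for gm in gene_models:
            paint[gm.span.chrom][gm.span.start : gm.span.end] = _T_NEUTRAL
        for li, lnc in enumerate(lncs):
            p = paint[lnc.chrom]
            o = owner[lnc.chrom]
            if lnc.flank_status is not None or (
                lnc.origin_class == "intergenic" and lnc.conserved
            ):
                flen = sum(e - s for s, e in lnc.blocks)
                code = _T_FLANK_CONS if lnc.flank_status == "conserved" else _T_RANDOMIZE
                p[max(0, lnc.start - flen) : lnc.start] = code
                p[lnc.end : lnc.end + flen] = code
            code = _T_LNC if lnc.conserved else _T_RANDOMIZE
            p[lnc.start : lnc.end] = code
            o[lnc.start : lnc.end] = li
        for gm in gene_models:
            for c in gm.cds:
                paint[c.chrom][c.start : c.end] = _T_CDS
                owner[c.chrom][c.start : c.end] = -1
        return {"paint": paint, "owner": owner}

    def _build_partner(
        self, tag, scale, arrs, cds_store, genes, lncs, gene_models, painted
    ) -> dict:
        cfg = self.cfg
        chrom_seqs = {}
        coord_maps = {}
        lnc_b: dict[str, tuple[int, int]] = {}
        kaks_truth = {}
        for chrom in self.chroms:
            paint = painted["paint"][chrom]
            owner = painted["owner"][chrom]
            a = np.array(list("".join(arrs[chrom])))
            L = len(a)
            # per-position substitution rates
            rate = np.full(L, min(0.5, 0.45 * scale))
            rate[paint == _T_NEUTRAL] = min(0.4, cfg.neutral_rate * scale)
            rate[paint == _T_FLANK_CONS] = min(0.45, cfg.flank_mutation_rate * scale)
            rate[paint == _T_CDS] = 0.0
            rate[paint == _T_RANDOMIZE] = 0.0
            for li, lnc in enumerate(lncs):
                if lnc.chrom == chrom and lnc.conserved:
                    r = min(0.35, (1.0 - lnc.target_identity) * scale)
                    rate[owner == li] = r
            rng = self._rng(f"subst/{tag}/{chrom}")
            u = rng.random(L)
            is_ts = rng.random(L) < 0.5
            tv_pick = rng.integers(0, 2, L)
            b = a.copy()
            hit = u < rate
            for i in np.flatnonzero(hit):
                base = a[i]
                if base not in TRANSITION:
                    continue
                if is_ts[i]:
                    b[i] = TRANSITION[base]
                else:
                    opts = [x for x in BASES if x != base and x != TRANSITION[base]]
                    b[i] = opts[tv_pick[i]]
            chrom_seqs[chrom] = b
        # codon-aware CDS mutation per gene
        for g, gm in zip(genes, genes and gene_models):
            cds_a = cds_store[g.gene_id]
            rng = self._rng(f"cds/{tag}/{g.gene_id}")
            cds_b, realized = mutate_cds(cds_a, g.target_kaks, cfg.ks_target * scale, rng)
            kaks_truth[g.gene_id] = {"target_kaks": g.target_kaks, **realized}
            positions = _cds_positions(gm)
            seq = cds_b if g.strand == "+" else revcomp(cds_b)
            lo = min(p for p in positions)
            b = chrom_seqs[g.chrom]
            idx = sorted(positions)
            for p, ch in zip(idx, seq):
                b[p] = ch
        # randomized regions
        for chrom in self.chroms:
            paint = painted["paint"][chrom]
            b = chrom_seqs[chrom]
            for s, e in _runs(paint == _T_RANDOMIZE):
                rnd = self._rng(f"rand/{tag}/{chrom}/{s}")
                b[s:e] = list(_random_seq(rnd, e - s, cfg.gc_content))
        # assembly with indels in filler, tracking coordinates
        genomes = {}
        for chrom in self.chroms:
            paint = painted["paint"][chrom]
            owner = painted["owner"][chrom]
            b = chrom_seqs[chrom]
            parts = []
            blen = 0
            cmap = []  # (a_start, a_end, b_start) for length-preserving runs
            rng = self._rng(f"indel/{tag}/{chrom}")
            key = paint.astype(np.int64) * (len(lncs) + 2) + (owner + 1)
            for s, e in _runs_of_equal(key):
                frag = "".join(b[s:e])
                if paint[s] == _T_FILLER and cfg.indel_rate > 0:
                    frag = _apply_indels(frag, cfg.indel_rate, rng)
                else:
                    cmap.append((s, e, blen))
                if owner[s] >= 0:
                    lnc = lncs[owner[s]]
                    lnc_b[lnc.lnc_id] = (blen, blen + len(frag))
                parts.append(frag)
                blen += len(frag)
            genomes[chrom] = "".join(parts)
            coord_maps[chrom] = cmap
        genome = GenomeRecord(species_tag=tag, chrom_sequences=genomes)
        # partner gene models through the coordinate map
        part_models = []
        for gm in gene_models:
            part_models.append(_remap_gene(gm, coord_maps[gm.span.chrom]))
        synteny = [
            SyntenyBlock(
                GenomeInterval(c, 0, self.cfg.chrom_length),
                GenomeInterval(c, 0, len(genomes[c])),
                "same",
            )
            for c in self.chroms
        ]
        return {
            "genome": genome,
            "genes": part_models,
            "synteny": synteny,
            "lnc_intervals": lnc_b,
            "kaks": kaks_truth,
        }

    # -- transcripts, cancer, truth -----------------------------------------

    def _transcripts(self, genome_a, gene_models, lncs) -> list[TranscriptRecord]:
        out = []
        cfg = self.cfg
        for gm in gene_models:
            if self._rng(f"mrna/{gm.gene_id}").random() < cfg.mrna_fraction:
                seq = _spliced_seq(genome_a, gm.span.chrom, [e.pair for e in gm.exons], gm.strand)
                out.append(TranscriptRecord(gm.transcript_id, seq, cfg.species_a))
        for lnc in lncs:
            seq = _spliced_seq(genome_a, lnc.chrom, lnc.blocks, lnc.strand)
            out.append(TranscriptRecord(lnc.lnc_id, seq, cfg.species_a))
        out.sort(key=lambda t: t.transcript_id)
        return out

    def build(self) -> ForgeResult:
        cfg = self.cfg
        genes, lncs = self._plan()
        arrs, cds_store = self._assemble_a(genes)
        self._apply_priming(arrs, lncs)
        gene_models = [self._gene_model(g) for g in genes]
        genome_a = GenomeRecord(
            species_tag=cfg.species_a,
            chrom_sequences={c: "".join(arrs[c]) for c in self.chroms},
        )
        painted = self._paint(genes, lncs, gene_models)
        partners = {}
        for tag in sorted(cfg.partners):
            partners[tag] = self._build_partner(
                tag, cfg.partners[tag], arrs, cds_store, genes, lncs, gene_models, painted
            )
        transcripts = self._transcripts(genome_a, gene_models, lncs)
        hosts = sorted({l.host_gene for l in lncs if l.host_gene})
        cancer_ids = set()
        for gm in gene_models:
            p = cfg.cancer_host_fraction if gm.gene_id in hosts else cfg.cancer_background_fraction
            if self._rng(f"cancer/{gm.gene_id}").random() < p:
                cancer_ids.add(gm.gene_id)
                gm.cancer_flag = True
        cancer = CancerGeneSet(cancer_ids, "forged CGMIM-like set")
        truth = {
            "species_a": cfg.species_a,
            "partners": dict(sorted(cfg.partners.items())),
            "hosts": hosts,
            "cancer_genes": sorted(cancer_ids),
            "lncrnas": [
                {
                    "id": l.lnc_id,
                    "origin_class": l.origin_class,
                    "chrom": l.chrom,
                    "blocks": [list(b) for b in l.blocks],
                    "strand": l.strand,
                    "host_gene": l.host_gene,
                    "conserved": l.conserved,
                    "target_identity": l.target_identity,
                    "priming_decoy": l.priming_decoy,
                    "antisense": l.antisense,
                    "spliced": l.spliced,
                    "flank_status": l.flank_status,
                    "orthologs": {
                        tag: list(part["lnc_intervals"].get(l.lnc_id, ()))
                        for tag, part in partners.items()
                    },
                }
                for l in lncs
            ],
            "genes": [
                {
                    "gene_id": gm.gene_id,
                    "chrom": gm.span.chrom,
                    "strand": gm.strand,
                    "cancer": gm.gene_id in cancer_ids,
                    "kaks": {tag: part["kaks"].get(gm.gene_id, {}) for tag, part in partners.items()},
                }
                for gm in gene_models
            ],
        }
        return ForgeResult(
            config=cfg,
            genome_a=genome_a,
            genes_a=gene_models,
            transcripts=transcripts,
            partners=partners,
            cancer=cancer,
            truth=truth,
        )


def _flip(strand: str) -> str:
    return "-" if strand == "+" else "+"


def _spliced_seq(genome: GenomeRecord, chrom: str, blocks, strand: str) -> str:
    fwd = "".join(genome.chrom_sequences[chrom][s:e] for s, e in sorted(blocks))
    return revcomp(fwd) if strand == "-" else fwd


def _cds_positions(gm: GeneModel) -> list[int]:
    pos = []
    for c in sorted(gm.cds, key=lambda x: x.start):
        pos.extend(range(c.start, c.end))
    return pos


def _apply_indels(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Small insertions/deletions (1-3 nt), applied per position at `rate`."""
    out = []
    for ch in seq:
        if rng.random() < rate:
            if rng.random() < 0.5:
                continue  # deletion
            out.append(ch)
            out.append(_random_seq(rng, int(rng.integers(1, 4))))
        else:
            out.append(ch)
    return "".join(out)


def _runs(mask: np.ndarray):
    idx = np.flatnonzero(np.diff(np.concatenate(([0], mask.astype(np.int8), [0]))))
    for s, e in zip(idx[::2], idx[1::2]):
        yield int(s), int(e)


def _runs_of_equal(key: np.ndarray):
    breaks = np.flatnonzero(np.diff(key)) + 1
    edges = np.concatenate(([0], breaks, [len(key)]))
    for s, e in zip(edges[:-1], edges[1:]):
        yield int(s), int(e)


def _remap_gene(gm: GeneModel, cmap: list[tuple[int, int, int]]) -> GeneModel:
    def conv(p: int) -> int:
        for a_s, a_e, b_s in cmap:
            if a_s <= p <= a_e:
                return b_s + (p - a_s)
        raise ForgeError(f"position {p} of {gm.gene_id} not in a conserved run")

    def conv_iv(ivl: GenomeInterval) -> GenomeInterval:
        return GenomeInterval(ivl.chrom, conv(ivl.start), conv(ivl.end), ivl.strand)

    model = GeneModel(
        gene_id=gm.gene_id,
        transcript_id=gm.transcript_id,
        span=conv_iv(gm.span),
        exons=[conv_iv(x) for x in gm.exons],
        cds=[conv_iv(x) for x in gm.cds],
        utr5=[conv_iv(x) for x in gm.utr5],
        utr3=[conv_iv(x) for x in gm.utr3],
    )
    model.validate()
    return model


# ---------------------------------------------------------------------------
# Spec-level convenience operations


def forge_gene_pair(config: ForgeConfig, rng: Optional[np.random.Generator] = None):
    """One orthologous gene pair with codon-aware divergence.

    Returns (gene_model_a, gene_model_b, realized) where realized carries the
    introduced-change accounting including the realized Ka/Ks.
    """
    config.validate()
    cfg = ForgeConfig(**{**asdict(config), "n_genes": 1, "n_antisense": 0,
                         "n_spliced_intergenic": 0,
                         "n_lnc_per_class": {}})
    res = Forge(cfg).build()
    tag = sorted(cfg.partners)[0]
    part = res.partners[tag]
    realized = part["kaks"][res.genes_a[0].gene_id]
    return res.genes_a[0], part["genes"][0], realized


def plant_lncrna(config: ForgeConfig, origin_class: str, rng=None):
    """Forge a minimal dataset holding one lncRNA of the requested class.

    Returns (TranscriptRecord, ground-truth entry, ForgeResult).
    """
    if origin_class not in ORIGIN_CLASSES:
        raise ForgeError(f"unknown origin class {origin_class!r}")
    n_genes = 1 if origin_class != "intergenic" else 0
    cfg = ForgeConfig(**{**asdict(config),
                         "n_genes": max(config.n_genes, n_genes),
                         "n_antisense": 0, "n_spliced_intergenic": 0,
                         "n_lnc_per_class": {origin_class: 1}})
    res = Forge(cfg).build()
    entry = next(e for e in res.truth["lncrnas"])
    tx = next(t for t in res.transcripts if t.transcript_id == entry["id"])
    return tx, entry, res


def emit_dataset(config: ForgeConfig, outdir: str | Path) -> Path:
    """Forge and write the full dataset directory."""
    return Forge(config).build().emit(outdir)
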