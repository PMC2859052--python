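"""Synteny projection, ortholog deduction, preservation codes, tallies."""

import numpy as np
import pytest

from lncsieve.alignment import AlignmentResult
from lncsieve.forge import _random_seq, _mutate_seq
from lncsieve.models import GenomeInterval, GenomeRecord, SyntenyBlock
from lncsieve.orthology import (
    OrthologHit,
    classify_conservation,
    find_ortholog,
    preservation_profile,
    syntenic_window,
)


def _block(s0, e0, s1, e1, orient="same"):
    return SyntenyBlock(GenomeInterval("chr1", s0, e0), GenomeInterval("chr1", s1, e1), orient)


# ---------------------------------------------------------------------------
# syntenic_window


def test_midpoint_maps_to_midpoint_same_orientation():
    b = _block(1000, 2000, 5000, 7000)  # 2x scale
    w = syntenic_window(GenomeInterval("chr1", 1450, 1550), [b], pad=0)
    assert (w.start, w.end) == (5900, 6100)


def test_inverted_block_mirrors_coordinates():
    b = _block(1000, 2000, 5000, 6000, "inverted")
    w = syntenic_window(GenomeInterval("chr1", 1000, 1100), [b], pad=0)
    assert (w.start, w.end) == (5900, 6000)
    w = syntenic_window(GenomeInterval("chr1", 1900, 2000), [b], pad=0)
    assert (w.start, w.end) == (5000, 5100)


def test_interval_outside_all_blocks_has_no_window():
    b = _block(1000, 2000, 5000, 6000)
    assert syntenic_window(GenomeInterval("chr1", 3000, 3100), [b]) is None


def test_pad_and_clipping():
    b = _block(1000, 2000, 5000, 6000)
    w = syntenic_window(GenomeInterval("chr1", 1000, 1100), [b], pad=10_000,
                        target_chrom_length=6500)
    assert w.start == 0 and w.end == 6500


def test_largest_overlap_block_wins():
    b1 = _block(0, 1000, 0, 1000)
    b2 = _block(1000, 3000, 10_000, 12_000)
    w = syntenic_window(GenomeInterval("chr1", 900, 1500), [b1, b2], pad=0)
    assert w.start >= 10_000  # mostly covered by b2


# ---------------------------------------------------------------------------
# find_ortholog


def _paired_genomes(identity=0.85, scramble=False, seed=0):
    rng = np.random.default_rng(seed)
    a = _random_seq(rng, 12_000)
    core = a[6000:6400]
    if scramble:
        counterpart = "".join(rng.permutation(list(core)))
    else:
        counterpart = _mutate_seq(core, 1 - identity, rng)
    b = _random_seq(rng, 6000) + counterpart + _random_seq(rng, 5600)
    ga = GenomeRecord("M", {"chr1": a})
    gb = GenomeRecord("H", {"chr1": b})
    synteny = [_block(0, 12_000, 0, len(b))]
    return ga, gb, synteny, core


def test_planted_85_percent_ortholog_is_homologous():
    ga, gb, synteny, core = _paired_genomes(identity=0.85)
    hit = find_ortholog("c", core, GenomeInterval("chr1", 6000, 6400), gb, synteny)
    assert hit.syntenic
    assert hit.homologous_at_1e2
    assert hit.target_interval.overlaps(GenomeInterval("chr1", 6000, 6400))


def test_scrambled_window_is_syntenic_but_not_homologous():
    ga, gb, synteny, core = _paired_genomes(scramble=True)
    hit = find_ortholog("c", core, GenomeInterval("chr1", 6000, 6400), gb, synteny)
    assert hit.syntenic
    assert not hit.homologous_at_1e2 and not hit.homologous_at_1e6


def test_no_synteny_block_yields_absent_hit():
    ga, gb, synteny, core = _paired_genomes()
    hit = find_ortholog("c", core, GenomeInterval("chr1", 100, 500), gb, [])
    assert not hit.syntenic and hit.hit is None


def test_homology_flag_implication_enforced():
    with pytest.raises(ValueError):
        OrthologHit("c", "H", None, True, homologous_at_1e6=True, homologous_at_1e2=False)


# ---------------------------------------------------------------------------
# preservation_profile


def _hit(conserved):
    res = AlignmentResult(100, 90.0, 0, 0, 0, 0, 1e-9 if conserved else 0.5, 100)
    return OrthologHit("c", "x", res, True, conserved, conserved)


def test_preservation_code_fixed_order():
    hits = {"D": _hit(True), "C": _hit(True), "H": _hit(True)}
    assert preservation_profile("M", hits) == "HMDC"
    hits2 = {"C": _hit(True), "H": _hit(True), "D": _hit(True)}
    assert preservation_profile("M", hits2) == "HMDC"


def test_preservation_code_partial_and_home_only():
    assert preservation_profile("M", {"H": _hit(True), "D": _hit(False)}) == "HM"
    assert preservation_profile("M", {}) == "M"


def test_preservation_on_forged_multispecies():
    from lncsieve.forge import Forge, ForgeConfig

    cfg = ForgeConfig(
        seed=21, n_genes=4, chrom_length=60_000,
        partners={"H": 1.0, "D": 1.3, "C": 1.5},
        n_lnc_per_class={"intergenic": 2}, n_antisense=0, n_spliced_intergenic=0,
        conserved_fraction=1.0, mrna_fraction=0.0,
    )
    res = Forge(cfg).build()
    codes = set()
    for t in res.transcripts:
        e = next(x for x in res.truth["lncrnas"] if x["id"] == t.transcript_id)
        s, en = e["blocks"][0]
        src = GenomeInterval(e["chrom"], s, en, e["strand"])
        hits = {}
        for tag, part in res.partners.items():
            hits[tag] = find_ortholog(t.transcript_id, t.sequence, src,
                                      part["genome"], part["synteny"])
        codes.add(preservation_profile("M", hits))
    assert codes == {"HMDC"}


# ---------------------------------------------------------------------------
# classify_conservation


def test_conservation_tallies_match_ground_truth(default_forge):
    from lncsieve.discovery import KmerIndex, map_transcript, classify_origin
    from lncsieve.models import LncRNACandidate

    res = default_forge
    idx = KmerIndex(res.genome_a)
    truth = {e["id"]: e for e in res.truth["lncrnas"]}
    cands, hits = [], {}
    part = res.partners["H"]
    for t in res.transcripts:
        if t.transcript_id not in truth:
            continue
        m = map_transcript(t, res.genome_a, index=idx)
        cls, host = classify_origin(m, res.genes_a)
        cands.append(LncRNACandidate(t.transcript_id, m, origin_class=cls,
                                     host_gene_id=host, exon_count=m.exon_count))
        hits[t.transcript_id] = find_ortholog(
            t.transcript_id, t.sequence, GenomeInterval(m.chrom, m.start, m.end, m.strand),
            part["genome"], part["synteny"],
        )
    tallies = classify_conservation(cands, hits)
    exp_coding = sum(1 for e in truth.values() if e["origin_class"] in ("utr_only", "intron_only", "mixed"))
    exp_spliced = sum(1 for e in truth.values() if e["spliced"])
    assert tallies["total"] == len(truth)
    assert tallies["protein_coding_region"] == exp_coding
    assert tallies["non_protein_coding_region"] == len(truth) - exp_coding
    assert tallies["spliced"] == exp_spliced
    assert (
        tallies["with_significant_homology"] + tallies["without_significant_homology"]
        == tallies["total"]
    )
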