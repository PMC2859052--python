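"""ORF scanning, NG86 Ka/Ks, protein homology gate, flank contrast."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from oracles import oracle_orfs

from lncsieve.forge import make_codon_pair, mutate_cds, _random_cds
from lncsieve.models import GenomeInterval, revcomp
from lncsieve.selection import (
    ORFRecord,
    classify_band,
    codon_pair_from_protein_alignment,
    kaks_contrast,
    kaks_ng86,
    protein_homology_gate,
    six_frame_orfs,
)

# ---------------------------------------------------------------------------
# Six-frame ORFs


def test_orf_hand_example():
    (orf,) = six_frame_orfs("ATGAAATAG")
    assert orf.frame == 1 and orf.protein == "MK"
    assert (orf.nt_start, orf.nt_end) == (0, 6)


def test_orf_no_atg_yields_empty():
    assert six_frame_orfs("CCC" * 20) == []


def test_orf_scan_matches_translation_oracle():
    rng = np.random.default_rng(5)
    for _ in range(100):
        seq = "".join(rng.choice(list("ACGT"), 300))
        got = {o.frame: o.protein for o in six_frame_orfs(seq)}
        assert got == oracle_orfs(seq), seq


def test_orf_coordinates_address_the_protein():
    rng = np.random.default_rng(6)
    for _ in range(20):
        seq = "".join(rng.choice(list("ACGT"), 200))
        for o in six_frame_orfs(seq):
            sub = seq[o.nt_start : o.nt_end]
            if o.frame < 0:
                sub = revcomp(sub)
            from Bio.Seq import Seq

            assert str(Seq(sub).translate()) == o.protein
            assert (o.nt_end - o.nt_start) % 3 == 0


def test_orf_stop_free_mode_covers_frames_without_atg():
    orfs = six_frame_orfs("CCCCCCCCCCCC", mode="stop_free")
    assert orfs and all("*" not in o.protein for o in orfs)


# ---------------------------------------------------------------------------
# NG86


def test_identical_cds_undefined_ratio():
    r = kaks_ng86("TTTTCTGAT", "TTTTCTGAT")
    assert r.ka == 0.0 and r.ks == 0.0
    assert r.undefined and r.ratio is None


def test_single_synonymous_change_hand_computed():
    # TTT(Phe) -> TTC(Phe): S sites per sequence = 1/3 + 1 + 1/3 = 5/3
    r = kaks_ng86("TTTTCTGAT", "TTCTCTGAT")
    assert r.nd == 0 and r.sd == 1
    assert r.s_sites == pytest.approx(5 / 3)
    assert r.ka == 0.0
    p = 1 / r.s_sites
    expected_ks = -0.75 * np.log(1 - 4 * p / 3)
    assert r.ks == pytest.approx(expected_ks)


def test_sites_partition_three_per_codon():
    rng = np.random.default_rng(2)
    a, b, _ = make_codon_pair(50, 0.5, rng=rng)
    r = kaks_ng86(a, b)
    assert r.s_sites + r.n_sites == pytest.approx(len(a))


def test_two_position_codon_difference_pathway_average():
    # single differing codon TTT -> GTA embedded in identical context;
    # oracle: enumerate both mutational orders by hand.
    #   TTT -(pos0)-> GTT(Val): nonsyn; GTT -(pos2)-> GTA(Val): syn
    #   TTT -(pos2)-> TTA(Leu): nonsyn; TTA -(pos0)-> GTA(Val): nonsyn
    # average: sd = (1+0)/2 = 0.5, nd = (1+2)/2 = 1.5
    r = kaks_ng86("AAATTT", "AAAGTA")
    assert r.sd == pytest.approx(0.5)
    assert r.nd == pytest.approx(1.5)


def test_pathways_through_stops_excluded():
    # TGT(Cys) -> TAC(Tyr): via TAT(Tyr) [syn+nonsyn] or via TGC(Cys) ...
    # TGT -(pos1)-> TAT: nonsyn; TAT -(pos2)-> TAC: syn
    # TGT -(pos2)-> TGC: syn;    TGC -(pos1)-> TAC: nonsyn
    # neither passes a stop -> average sd=1, nd=1; now force a stop pathway:
    # TCA(Ser) -> TTG(Leu): via TTA(Leu) nonsyn+syn, or via TCG(Ser) syn+nonsyn
    r = kaks_ng86("TCA", "TTG")
    assert r.sd == pytest.approx(1.0) and r.nd == pytest.approx(1.0)
    # TAT(Tyr) -> TGG(Trp): via TGT(Cys) = nonsyn+nonsyn,
    # via TAG(stop) -> excluded; only one valid pathway remains
    r = kaks_ng86("TAT", "TGG")
    assert r.sd == 0.0 and r.nd == 2.0


@settings(max_examples=60, derandomize=True, deadline=None)
@given(st.integers(0, 2**32 - 1))
def test_kaks_symmetric(seed):
    rng = np.random.default_rng(seed)
    a, b, _ = make_codon_pair(20, 1.0, rng=rng)
    r1, r2 = kaks_ng86(a, b), kaks_ng86(b, a)
    assert r1.sd == pytest.approx(r2.sd) and r1.nd == pytest.approx(r2.nd)
    assert r1.s_sites == pytest.approx(r2.s_sites)
    assert (r1.ratio is None) == (r2.ratio is None)
    if r1.ratio is not None:
        assert r1.ratio == pytest.approx(r2.ratio)


def test_kaks_agrees_with_biopython_ng86():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        from Bio.codonalign.codonseq import CodonSeq, cal_dn_ds
    for seed in range(5):
        a, b, _ = make_codon_pair(150, 0.5, rng=np.random.default_rng(seed))
        dn, ds = cal_dn_ds(CodonSeq(a), CodonSeq(b), method="NG86")
        mine = kaks_ng86(a, b)
        assert mine.ka == pytest.approx(dn, abs=1e-6)
        assert mine.ks == pytest.approx(ds, abs=1e-6)


def test_kaks_recovers_forged_ratios():
    """NG86 within +-0.15 of the forged value (300 codons, p<0.3, 20 seeds)."""
    for seed in range(20):
        rng = np.random.default_rng(seed)
        for target in (0.2, 1.0):
            a, b, realized = make_codon_pair(300, target, ks_target=0.25, rng=rng)
            p = sum(x != y for x, y in zip(a, b)) / len(a)
            assert p < 0.3
            est = kaks_ng86(a, b)
            assert est.ratio == pytest.approx(realized["realized_kaks"], abs=0.15)


def test_kaks_rejects_internal_stop_and_bad_length():
    with pytest.raises(ValueError):
        kaks_ng86("TAAAAA", "TAAAAA")
    with pytest.raises(ValueError):
        kaks_ng86("AAAA", "AAAA")
    with pytest.raises(ValueError):
        kaks_ng86("AAA", "AAAAAA")


def test_band_classification():
    assert classify_band(0.2) == "purifying"
    assert classify_band(0.5) == "neutral"
    assert classify_band(1.5) == "neutral"
    assert classify_band(2.0) == "diversifying"
    assert classify_band(None) == "undefined"


# ---------------------------------------------------------------------------
# Protein homology gate


def _orf(protein: str) -> ORFRecord:
    return ORFRecord(frame=1, nt_start=0, nt_end=3 * len(protein), protein=protein)


def test_identical_proteins_pass_gate():
    p = "MKLVINSEQWLRTAGHDEFYCPKMKLVINSEQWLRTAGHDEFYCPKMKLV"
    assert protein_homology_gate(_orf(p), _orf(p))


def test_unrelated_random_proteins_fail_with_high_probability():
    rng = np.random.default_rng(9)
    aas = list("ACDEFGHIKLMNPQRSTVWY")
    fails = 0
    for _ in range(100):
        p1 = "".join(rng.choice(aas, 50))
        p2 = "".join(rng.choice(aas, 50))
        if not protein_homology_gate(_orf(p1), _orf(p2)):
            fails += 1
    assert fails >= 95


def test_short_protein_violates_precondition():
    with pytest.raises(ValueError):
        protein_homology_gate(_orf("MKLVINSEQ"), _orf("MKLVINSEQWL"))


# ---------------------------------------------------------------------------
# Ka/Ks contrast


def _embed(cds: str, rng) -> str:
    tail = "".join(rng.choice(list("ACGT"), 30))
    head = "".join(rng.choice(list("ACGT"), 30))
    return head + cds + tail


def test_kaks_contrast_neutral_lnc_vs_purifying_parent():
    rng = np.random.default_rng(12)
    core_a = _random_cds(rng, 300)
    core_b, _ = mutate_cds(core_a, 1.0, 0.25, rng)
    lnc_a, lnc_b = _embed(core_a, rng), _embed(core_b, rng)
    par_a = _random_cds(rng, 150)[3:-3]
    par_b = mutate_cds("ATG" + par_a + "TAA", 0.1, 0.25, rng)[0][3:-3]
    (row,) = kaks_contrast([("x", lnc_a, lnc_b)], [("x", par_a, par_b)])
    assert row["band_lnc"] == "neutral"
    assert row["band_parent"] == "purifying"


def test_kaks_contrast_no_orf_reported():
    (row,) = kaks_contrast([("x", "CCCT" * 60, "CCCT" * 60)], [])
    assert row["band_lnc"] == "no ORF homology"
    assert row["band_parent"] == "no parent"


def test_kaks_contrast_ks_zero_propagates_undefined():
    rng = np.random.default_rng(3)
    cds = _random_cds(rng, 80)[0:-3]
    rows = kaks_contrast([("x", "A" * 10, "A" * 10)], [("x", cds, cds)])
    assert rows[0]["band_lnc"] == "no ORF homology"
    assert rows[0]["band_parent"] == "undefined"
    assert rows[0]["kaks_parent"] is None


def test_codon_backtranslation_round_trip():
    rng = np.random.default_rng(4)
    core = _random_cds(rng, 40)
    t = _embed(core, rng)
    orfs = [o for o in six_frame_orfs(t) if o.protein.startswith("M")]
    o = max(orfs, key=lambda x: x.length_aa)
    ca, cb = codon_pair_from_protein_alignment(o, o, t, t)
    assert ca == cb and len(ca) % 3 == 0 and len(ca) > 0


# ---------------------------------------------------------------------------
# Flank contrast (on forged data)


def test_flank_ordering_when_flanks_mutate_faster(default_forge):
    """Conserved lncRNAs outscore their flanks when flanks diverge faster.

    A planted "not conserved" flank can still pick up a rare spurious local
    hit (the e < 0.01 threshold admits ~1-2% chance hits per buffer), so the
    forge-wide assertion is the identity ordering; the exact
    flank_conserved=False behavior is pinned on a controlled pair below.
    """
    from lncsieve.orthology import find_ortholog
    from lncsieve.selection import flank_contrast

    res = default_forge
    part = res.partners["H"]
    truth = {e["id"]: e for e in res.truth["lncrnas"]}
    checked = 0
    for t in res.transcripts:
        e = truth.get(t.transcript_id)
        if not e or not e["conserved"] or e["origin_class"] != "intergenic" or e["spliced"]:
            continue
        s, en = e["blocks"][0]
        src = GenomeInterval(e["chrom"], s, en, e["strand"])
        hit = find_ortholog(t.transcript_id, t.sequence, src, part["genome"], part["synteny"])
        fc = flank_contrast(t.transcript_id, src, hit, res.genome_a, part["genome"], part["synteny"])
        assert fc.lnc_identity > (fc.flank_identity or 0.0)
        checked += 1
    assert checked >= 1


def test_randomized_flanks_report_not_conserved():
    """Conserved core with fully randomized flanks: the Table-2 'not conserved' row."""
    from lncsieve.forge import _mutate_seq, _random_seq
    from lncsieve.models import GenomeRecord, SyntenyBlock
    from lncsieve.orthology import find_ortholog
    from lncsieve.selection import flank_contrast

    rng = np.random.default_rng(17)
    a = _random_seq(rng, 12_000)
    core = a[6000:6400]
    b = _random_seq(rng, 6000) + _mutate_seq(core, 0.12, rng) + _random_seq(rng, 5600)
    ga = GenomeRecord("M", {"chr1": a})
    gb = GenomeRecord("H", {"chr1": b})
    synteny = [SyntenyBlock(GenomeInterval("chr1", 0, 12_000), GenomeInterval("chr1", 0, len(b)))]
    src = GenomeInterval("chr1", 6000, 6400)
    hit = find_ortholog("c", core, src, gb, synteny)
    assert hit.homologous_at_1e2
    fc = flank_contrast("c", src, hit, ga, gb, synteny)
    assert not fc.flank_conserved
    assert fc.flank_identity is None
    assert fc.lnc_identity > 80.0
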