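"""Folding DP against a structure-enumeration oracle; shuffle z-score; SCI."""

from collections import Counter

import numpy as np
import pytest

from oracles import no_lonely, oracle_fold

from lncsieve.forge import make_hairpin, make_hairpin_pair, make_unstructured_pair
from lncsieve.structure import (
    MIN_LOOP,
    StructureReport,
    classify_structured,
    dinucleotide_shuffle,
    evaluate_pair,
    fold_score,
    pair_weight,
    shuffle_zscore,
    structural_conservation_index,
)


def test_fold_no_complementary_pairs():
    score, db = fold_score("AAAAAAAAAA")
    assert score == 0 and db == "." * 10


def test_fold_perfect_gc_hairpin():
    score, db = fold_score("GGGGAAAACCCC")
    assert score == 12
    assert db == "((((....))))"


def test_fold_matches_enumeration_oracle():
    rng = np.random.default_rng(8)
    for _ in range(25):
        n = int(rng.integers(10, 15))
        seq = "".join(rng.choice(list("ACGT"), n))
        score, db = fold_score(seq)
        assert score == oracle_fold(seq), seq
        # reported structure is valid and achieves the reported score
        stack, pairs = [], []
        for i, c in enumerate(db):
            if c == "(":
                stack.append(i)
            elif c == ")":
                pairs.append((stack.pop(), i))
        assert not stack
        assert sum(pair_weight(seq[i], seq[j]) for i, j in pairs) == score
        assert all(j - i > MIN_LOOP for i, j in pairs)
        assert no_lonely(pairs)


def test_fold_rejects_short_sequences():
    with pytest.raises(ValueError):
        fold_score("ACGTACGTA")


def test_hairpin_beats_its_shuffles():
    seq = make_hairpin(stem=15, loop=6, tail=10, rng=np.random.default_rng(0))
    obs, _ = fold_score(seq)
    rng = np.random.default_rng(1)
    for _ in range(50):
        s, _ = fold_score(dinucleotide_shuffle(seq, rng))
        assert s < obs


# ---------------------------------------------------------------------------
# Dinucleotide shuffle


def test_shuffle_preserves_dinucleotide_counts_exactly():
    rng = np.random.default_rng(3)
    for _ in range(20):
        n = int(rng.integers(20, 200))
        seq = "".join(rng.choice(list("ACGT"), n))
        shuf = dinucleotide_shuffle(seq, rng)
        assert Counter(zip(seq, seq[1:])) == Counter(zip(shuf, shuf[1:]))
        assert shuf[0] == seq[0] and shuf[-1] == seq[-1]


def test_shuffle_actually_shuffles():
    rng = np.random.default_rng(4)
    seq = "".join(rng.choice(list("ACGT"), 200))
    assert any(dinucleotide_shuffle(seq, rng) != seq for _ in range(5))


# ---------------------------------------------------------------------------
# Z-score


def test_homopolymer_zscore_degenerate():
    z, degenerate = shuffle_zscore("A" * 50, n_shuffles=30, seed=0)
    assert z == 0.0 and degenerate


def test_zscore_requires_enough_shuffles():
    with pytest.raises(ValueError):
        shuffle_zscore("ACGT" * 20, n_shuffles=10)


def test_planted_hairpin_scores_high_z():
    for seed in range(10):
        seq = make_hairpin(stem=25, loop=8, tail=20, rng=np.random.default_rng(seed))
        z, degenerate = shuffle_zscore(seq, n_shuffles=100, seed=seed)
        assert not degenerate
        assert z >= 3.0


def test_random_sequence_z_mostly_small():
    rng = np.random.default_rng(5)
    small = 0
    for seed in range(100):
        seq = "".join(rng.choice(list("ACGT"), 80))
        z, _ = shuffle_zscore(seq, n_shuffles=30, seed=seed)
        if abs(z) <= 2:
            small += 1
    assert small >= 90


# ---------------------------------------------------------------------------
# Structural conservation index


def test_sci_identical_sequences_is_one():
    seq = make_hairpin(rng=np.random.default_rng(1))
    sci, degenerate = structural_conservation_index(seq, seq)
    assert not degenerate
    assert sci == pytest.approx(1.0)


def test_sci_scrambled_partner_low():
    """A scrambled partner destroys structural conservation.

    SCI of hairpin-vs-scramble is typically < 0.5 and always falls below
    the 0.7 classification threshold (well separated from compensatory
    pairs); the exact value fluctuates with the scramble.
    """
    vals = []
    for seed in range(8):
        rng = np.random.default_rng(seed)
        seq = make_hairpin(stem=25, loop=8, tail=10, rng=rng)
        scrambled = "".join(rng.permutation(list(seq)))
        sci, _ = structural_conservation_index(seq, scrambled)
        vals.append(sci)
    assert float(np.median(vals)) < 0.5
    assert max(vals) < 0.7


def test_sci_compensatory_substitutions_near_one():
    a, b = make_hairpin_pair(stem=25, loop=8, tail=10, n_compensatory=6,
                             rng=np.random.default_rng(6))
    sci, _ = structural_conservation_index(a, b)
    assert sci >= 0.8


def test_sci_degenerate_when_no_structure():
    sci, degenerate = structural_conservation_index("A" * 30, "A" * 30)
    assert sci == 0.0 and degenerate


# ---------------------------------------------------------------------------
# Classification


def test_classify_thresholds():
    mk = lambda z, sci, zd=False, sd=False: StructureReport("x", 10, z, sci, False, zd, sd)
    assert classify_structured(mk(3.5, 0.9))
    assert not classify_structured(mk(3.5, 0.2))
    assert not classify_structured(mk(1.0, 0.9))
    assert not classify_structured(mk(3.5, 0.9, zd=True))


def test_screen_separates_planted_positives_and_negatives():
    """Recall and specificity 1.0 on forged pairs over 10 seeds."""
    for seed in range(10):
        a, b = make_hairpin_pair(stem=25, loop=8, tail=15, n_compensatory=4,
                                 rng=np.random.default_rng(seed))
        rep = evaluate_pair("pos", a, b, n_shuffles=100, seed=seed)
        assert rep.structured, (seed, rep)
        a, b = make_unstructured_pair(n=100, rate=0.1, rng=np.random.default_rng(seed))
        rep = evaluate_pair("neg", a, b, n_shuffles=100, seed=seed)
        assert not rep.structured, (seed, rep)
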