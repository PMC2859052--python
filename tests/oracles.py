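"""Independent oracles shared by the unit and acceptance tests.

These deliberately avoid the package's DP formulations: alignments are
checked by path enumeration (global) and a memoized three-state recursion
(local affine); folding by enumeration of every nested pairing; ORFs by
Biopython translation plus a regex scan.
"""

import re
from functools import lru_cache

from lncsieve.models import revcomp
from lncsieve.structure import MIN_LOOP, pair_weight

MATCH, MISMATCH, GAP = 1, -2, -2
GO, GE = -5, -2  # affine: gap of length k costs GO + k*GE


# ---------------------------------------------------------------------------
# Alignment


def enumerate_global(a: str, b: str):
    """Every global alignment as a list of column pairs."""
    if not a and not b:
        yield []
        return
    if a:
        for rest in enumerate_global(a[1:], b):
            yield [(a[0], "-")] + rest
    if b:
        for rest in enumerate_global(a, b[1:]):
            yield [("-", b[0])] + rest
    if a and b:
        for rest in enumerate_global(a[1:], b[1:]):
            yield [(a[0], b[0])] + rest


def score_linear(cols):
    s = 0
    for x, y in cols:
        if x == "-" or y == "-":
            s += GAP
        else:
            s += MATCH if x == y else MISMATCH
    return s


def oracle_global(a: str, b: str) -> int:
    return max(score_linear(c) for c in enumerate_global(a, b))


def oracle_local_affine(a: str, b: str) -> int:
    """Memoized three-state recursion for local alignment with affine gaps."""

    @lru_cache(maxsize=None)
    def best(i, j, state):
        if state == "M":
            if i == 0 or j == 0:
                return None
            sub = MATCH if a[i - 1] == b[j - 1] else MISMATCH
            prev = [0]
            for st in "MEF":
                v = best(i - 1, j - 1, st)
                if v is not None:
                    prev.append(v)
            return max(prev) + sub
        if state == "E":
            if j == 0:
                return None
            opts = [0 + GO + GE]
            v = best(i, j - 1, "E")
            if v is not None:
                opts.append(v + GE)
            for st in "MF":
                v = best(i, j - 1, st)
                if v is not None:
                    opts.append(v + GO + GE)
            return max(opts)
        if i == 0:
            return None
        opts = [0 + GO + GE]
        v = best(i - 1, j, "F")
        if v is not None:
            opts.append(v + GE)
        for st in "ME":
            v = best(i - 1, j, st)
            if v is not None:
                opts.append(v + GO + GE)
        return max(opts)

    out = 0
    for i in range(len(a) + 1):
        for j in range(len(b) + 1):
            for st in "MEF":
                v = best(i, j, st)
                if v is not None and v > out:
                    out = v
    return out


# ---------------------------------------------------------------------------
# Folding


def all_structures(n):
    """All sets of nested (i, j) pairs with j - i > MIN_LOOP."""

    def rec(positions):
        if not positions:
            yield []
            return
        first, rest = positions[0], positions[1:]
        yield from rec(rest)
        for idx, j in enumerate(rest):
            if j - first > MIN_LOOP:
                inside = rest[:idx]
                outside = rest[idx + 1 :]
                for si in rec(inside):
                    for so in rec(outside):
                        yield [(first, j)] + si + so

    yield from rec(list(range(n)))


def no_lonely(struct):
    pairs = set(struct)
    return all((i + 1, j - 1) in pairs or (i - 1, j + 1) in pairs for i, j in struct)


def oracle_fold(seq: str) -> int:
    best = 0
    for struct in all_structures(len(seq)):
        if not all(pair_weight(seq[i], seq[j]) > 0 for i, j in struct):
            continue
        if not no_lonely(struct):
            continue
        best = max(best, sum(pair_weight(seq[i], seq[j]) for i, j in struct))
    return best


# ---------------------------------------------------------------------------
# ORFs


def oracle_orfs(seq: str):
    """Longest ATG..stop ORF per frame via Biopython translation + regex."""
    from Bio.Seq import Seq

    out = {}
    for sense, s in ((1, seq), (-1, revcomp(seq))):
        for off in range(3):
            sub = s[off : off + 3 * ((len(s) - off) // 3)]
            if not sub:
                continue
            prot = str(Seq(sub).translate())
            best = None
            for m in re.finditer(r"M[^*]*(?=\*)", prot):
                if best is None or len(m.group()) > len(best.group()):
                    best = m
            if best:
                out[sense * (off + 1)] = best.group()
    return out
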