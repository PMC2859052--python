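"""Half-open interval arithmetic on (start, end) pairs.

All coordinates in the package are 0-based half-open; these helpers operate on
plain integer pairs so callers can use them on any chromosome-local feature
lists without carrying strand or chromosome around.
"""

from __future__ import annotations

Pair = tuple[int, int]


def merge(ivs: list[Pair]) -> list[Pair]:
    """Sort and merge overlapping or touching intervals."""
    if not ivs:
        return []
    ivs = sorted(ivs)
    out = [ivs[0]]
    for s, e in ivs[1:]:
        ps, pe = out[-1]
        if s <= pe:
            out[-1] = (ps, max(pe, e))
        else:
            out.append((s, e))
    return out


def total_length(ivs: list[Pair]) -> int:
    return sum(e - s for s, e in merge(ivs))


def intersect(a: list[Pair], b: list[Pair]) -> list[Pair]:
    """Intersection of two interval sets (result merged and sorted)."""
    a, b = merge(a), merge(b)
    out: list[Pair] = []
    i = j = 0
    while i < len(a) and j < len(b):
        s = max(a[i][0], b[j][0])
        e = min(a[i][1], b[j][1])
        if s < e:
            out.append((s, e))
        if a[i][1] < b[j][1]:
            i += 1
        else:
            j += 1
    return out


def subtract(a: list[Pair], b: list[Pair]) -> list[Pair]:
    """Set difference a \\ b."""
    a, b = merge(a), merge(b)
    out: list[Pair] = []
    j = 0
    for s, e in a:
        cur = s
        while j < len(b) and b[j][1] <= cur:
            j += 1
        k = j
        while k < len(b) and b[k][0] < e:
            bs, be = b[k]
            if bs > cur:
                out.append((cur, bs))
            cur = max(cur, be)
            if be >= e:
                break
            k += 1
        if cur < e:
            out.append((cur, e))
    return out


def overlap_length(a: list[Pair], b: list[Pair]) -> int:
    return total_length(intersect(a, b))


def contained_in(a: list[Pair], b: list[Pair]) -> bool:
    """True iff the footprint of a is entirely within the footprint of b."""
    return total_length(subtract(a, b)) == 0


def gap_to(ivs: list[Pair], point_iv: Pair) -> int:
    """Smallest gap (0 if overlapping) between point_iv and any interval."""
    best = None
    s, e = point_iv
    for bs, be in ivs:
        if e > bs and s < be:
            return 0
        d = bs - e if bs >= e else s - be
        best = d if best is None else min(best, d)
    return best if best is not None else -1
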