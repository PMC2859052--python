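"""Secondary-structure screen: stability z-score and structural conservation.

A self-contained analogue of SVM-based structure screens: instead of a trained
"RNA class probability", two defined, desk-verifiable ingredients are computed
and thresholded:

* thermodynamic-stability proxy -- maximum-weight nested base pairing
  (Nussinov-style dynamic programming; AU/GU/GC pair weights 2/1/3, minimum
  hairpin loop 3), normalized against dinucleotide-preserving shuffles as a
  z-score;
* structural conservation index (SCI) -- consensus fold score of an aligned
  ortholog pair divided by the mean of the individual fold scores, near 1
  when the two sequences support the same pairing (including compensatory
  double substitutions) and near 0 when structure is not conserved.

A candidate is called "structured" when both ingredients clear their
thresholds (defaults z >= 2 and SCI >= 0.7). This is an analogue of, not a
reimplementation of, probability-based screens such as RNAz.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from lncsieve._kernels import nussinov_fill
from lncsieve.alignment import GlobalAlignment, global_align

MIN_LOOP = 3
PAIR_WEIGHTS = {
    ("A", "T"): 2, ("T", "A"): 2,
    ("G", "T"): 1, ("T", "G"): 1,
    ("G", "C"): 3, ("C", "G"): 3,
}


@dataclass
class StructureReport:
    candidate_id: str
    fold_score: float
    zscore: float
    sci: float
    structured: bool
    z_degenerate: bool = False
    sci_degenerate: bool = False


def _norm(seq: str) -> str:
    return seq.upper().replace("U", "T")


def pair_weight(a: str, b: str) -> int:
    return PAIR_WEIGHTS.get((a, b), 0)


def _weight_matrix(seq: str) -> np.ndarray:
    n = len(seq)
    w = np.zeros((n, n), dtype=np.int32)
    for i in range(n):
        for j in range(i + MIN_LOOP + 1, n):
            w[i, j] = pair_weight(seq[i], seq[j])
    return w


def _traceback(W: np.ndarray, A: np.ndarray, w: np.ndarray) -> str:
    """Deterministic traceback: prefer pairing, then advancing the smaller index."""
    n = W.shape[0]
    db = ["."] * n
    stack = [(0, n - 1, "W")]
    while stack:
        i, j, mode = stack.pop()
        if j - i <= MIN_LOOP:
            continue
        if mode == "A":
            db[i], db[j] = "(", ")"
            inner = A[i, j] - w[i, j]
            if A[i + 1, j - 1] == inner:
                stack.append((i + 1, j - 1, "A"))
            else:  # (i+1, j-1) closes the helix
                db[i + 1], db[j - 1] = "(", ")"
                if j - 2 - (i + 2) > MIN_LOOP:
                    stack.append((i + 2, j - 2, "W"))
            continue
        if W[i, j] == 0:
            continue
        if A[i, j] == W[i, j]:
            stack.append((i, j, "A"))
        elif W[i, j] == W[i + 1, j]:
            stack.append((i + 1, j, "W"))
        elif W[i, j] == W[i, j - 1]:
            stack.append((i, j - 1, "W"))
        else:
            for k in range(i + 1, j):
                if W[i, k] + W[k + 1, j] == W[i, j]:
                    stack.append((k + 1, j, "W"))
                    stack.append((i, k, "W"))
                    break
    return "".join(db)


def fold_score(seq: str, with_structure: bool = True) -> tuple[int, str]:
    """Maximum-weight stacked pairing score and its dot-bracket structure.

    Isolated pairs are disallowed (every helix is >= 2 stacked pairs), so
    the score reflects stable stacked structure rather than the promiscuous
    single pairings that any sequence can form.
    """
    seq = _norm(seq)
    if len(seq) < 10:
        raise ValueError("fold_score requires length >= 10")
    w = _weight_matrix(seq)
    W, A = nussinov_fill(w, MIN_LOOP)
    score = int(W[0, len(seq) - 1])
    return score, (_traceback(W, A, w) if with_structure else "." * len(seq))


# ---------------------------------------------------------------------------
# Dinucleotide-preserving shuffle (Altschul-Erickson Euler-path method)


def dinucleotide_shuffle(seq: str, rng: np.random.Generator) -> str:
    """A shuffle of seq preserving all 16 dinucleotide counts exactly."""
    seq = _norm(seq)
    if len(seq) < 3:
        return seq
    last = seq[-1]
    edges: dict[str, list[str]] = {}
    for a, b in zip(seq, seq[1:]):
        edges.setdefault(a, []).append(b)
    vertices = [v for v in edges if v != last]
    # choose last exit edges forming an arborescence toward the final vertex
    for _ in range(10000):
        chosen = {v: edges[v][rng.integers(len(edges[v]))] for v in vertices}
        ok = True
        for v in vertices:
            seen = {v}
            cur = v
            while cur != last:
                cur = chosen.get(cur)
                if cur is None or cur in seen:
                    ok = False
                    break
                seen.add(cur)
            if not ok:
                break
        if ok:
            break
    else:  # pragma: no cover - cannot happen for a walkable sequence
        raise RuntimeError("failed to sample an Eulerian arborescence")
    lists = {}
    for v, dests in edges.items():
        rest = list(dests)
        if v in chosen:
            rest.remove(chosen[v])
        perm = [rest[i] for i in rng.permutation(len(rest))] if rest else []
        if v in chosen:
            perm.append(chosen[v])
        lists[v] = perm
    out = [seq[0]]
    ptr = {v: 0 for v in lists}
    cur = seq[0]
    for _ in range(len(seq) - 1):
        nxt = lists[cur][ptr[cur]]
        ptr[cur] += 1
        out.append(nxt)
        cur = nxt
    return "".join(out)


def shuffle_zscore(
    seq: str, n_shuffles: int = 100, seed: int = 0
) -> tuple[float, bool]:
    """Stability z-score of the fold against dinucleotide-preserving shuffles.

    Returns (z, degenerate); degenerate is True when the shuffle distribution
    has zero spread (e.g. homopolymers), in which case z is reported as 0.
    """
    if n_shuffles < 30:
        raise ValueError("n_shuffles must be >= 30")
    obs, _ = fold_score(seq, with_structure=False)
    rng = np.random.default_rng(seed)
    scores = np.empty(n_shuffles)
    for k in range(n_shuffles):
        shuf = dinucleotide_shuffle(seq, rng)
        scores[k], _ = fold_score(shuf, with_structure=False)
    sd = float(np.std(scores, ddof=1))
    if sd == 0.0:
        return 0.0, True
    return float((obs - np.mean(scores)) / sd), False


# ---------------------------------------------------------------------------
# Structural conservation index


def structural_conservation_index(
    seq_a: str,
    seq_b: str,
    alignment: Optional[GlobalAlignment] = None,
) -> tuple[float, bool]:
    """Consensus fold score over both sequences / mean individual fold score.

    A column pair (i, j) contributes only when the bases of BOTH sequences at
    those columns can pair under the weight table (gap columns never pair);
    its consensus weight is the mean of the two individual pair weights.
    Returns (sci, degenerate); degenerate when the mean individual score is 0.
    """
    seq_a, seq_b = _norm(seq_a), _norm(seq_b)
    if alignment is None:
        alignment = global_align(seq_a, seq_b)
    qa, qb = alignment.aligned_query, alignment.aligned_target
    n = len(qa)
    w = np.zeros((n, n), dtype=np.int32)
    for i in range(n):
        if qa[i] == "-" or qb[i] == "-":
            continue
        for j in range(i + MIN_LOOP + 1, n):
            if qa[j] == "-" or qb[j] == "-":
                continue
            wa = pair_weight(qa[i], qa[j])
            wb = pair_weight(qb[i], qb[j])
            if wa > 0 and wb > 0:
                w[i, j] = wa + wb  # 2x mean, kept integral for the DP
    W, _ = nussinov_fill(w, MIN_LOOP)
    consensus = float(W[0, n - 1]) / 2.0
    ind_a, _ = fold_score(seq_a, with_structure=False)
    ind_b, _ = fold_score(seq_b, with_structure=False)
    mean_ind = (ind_a + ind_b) / 2.0
    if mean_ind == 0.0:
        return 0.0, True
    return consensus / mean_ind, False


def classify_structured(
    report: StructureReport, z_min: float = 2.0, sci_min: float = 0.7
) -> bool:
    if report.z_degenerate or report.sci_degenerate:
        return False
    return report.zscore >= z_min and report.sci >= sci_min


def evaluate_pair(
    candidate_id: str,
    seq_a: str,
    seq_b: str,
    n_shuffles: int = 100,
    seed: int = 0,
    z_min: float = 2.0,
    sci_min: float = 0.7,
) -> StructureReport:
    """Full structure screen for one ortholog pair (fold, z-score, SCI, call)."""
    score, _ = fold_score(seq_a, with_structure=False)
    z, z_deg = shuffle_zscore(seq_a, n_shuffles=n_shuffles, seed=seed)
    sci, s_deg = structural_conservation_index(seq_a, seq_b)
    rep = StructureReport(
        candidate_id=candidate_id,
        fold_score=score,
        zscore=z,
        sci=sci,
        structured=False,
        z_degenerate=z_deg,
        sci_degenerate=s_deg,
    )
    rep.structured = classify_structured(rep, z_min=z_min, sci_min=sci_min)
    return rep
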