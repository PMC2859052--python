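"""Numba-compiled dynamic-programming kernels.

These are the numeric cores of the global aligner (Needleman-Wunsch, linear
gap), the local aligner (Gotoh affine-gap Smith-Waterman) and the base-pair
maximization folder. Sequences arrive as small integer codes; substitution
scores arrive as dense matrices, so the same kernels serve nucleotide and
protein alphabets.
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG = -(10**8)


@njit(cache=False)
def nw_fill(a, b, submat, gap):
    """Global alignment score matrix, linear gap penalty (gap < 0)."""
    n, m = a.shape[0], b.shape[0]
    H = np.empty((n + 1, m + 1), dtype=np.int32)
    H[0, 0] = 0
    for j in range(1, m + 1):
        H[0, j] = gap * j
    for i in range(1, n + 1):
        H[i, 0] = gap * i
        ai = a[i - 1]
        for j in range(1, m + 1):
            d = H[i - 1, j - 1] + submat[ai, b[j - 1]]
            u = H[i - 1, j] + gap
            l = H[i, j - 1] + gap
            best = d
            if u > best:
                best = u
            if l > best:
                best = l
            H[i, j] = best
    return H


@njit(cache=False)
def sw_fill(a, b, submat, gap_open, gap_extend):
    """Gotoh local alignment; a gap of length k costs gap_open + k*gap_extend.

    Returns (H, E, F, best_score, best_i, best_j) where E holds gap-in-query
    (horizontal) states and F gap-in-target (vertical) states.
    """
    n, m = a.shape[0], b.shape[0]
    H = np.zeros((n + 1, m + 1), dtype=np.int32)
    E = np.full((n + 1, m + 1), NEG, dtype=np.int32)
    F = np.full((n + 1, m + 1), NEG, dtype=np.int32)
    best = 0
    bi = 0
    bj = 0
    for i in range(1, n + 1):
        ai = a[i - 1]
        for j in range(1, m + 1):
            e = E[i, j - 1] + gap_extend
            eo = H[i, j - 1] + gap_open + gap_extend
            if eo > e:
                e = eo
            E[i, j] = e
            f = F[i - 1, j] + gap_extend
            fo = H[i - 1, j] + gap_open + gap_extend
            if fo > f:
                f = fo
            F[i, j] = f
            h = H[i - 1, j - 1] + submat[ai, b[j - 1]]
            if e > h:
                h = e
            if f > h:
                h = f
            if h < 0:
                h = 0
            H[i, j] = h
            if h > best:
                best = h
                bi = i
                bj = j
    return H, E, F, best, bi, bj


@njit(cache=False)
def nussinov_fill(w, min_loop):
    """Maximum-weight nested pairing with no isolated pairs.

    w is an n*n pair-weight matrix (0 = not pairable); pairs (i, j) require
    j - i > min_loop and must sit in helices of >= 2 stacked pairs, so the
    score rewards stacked structure rather than promiscuous single pairs.
    Returns (W, A): W[i, j] is the best score on [i, j]; A[i, j] is the best
    score given that (i, j) opens a helix (NEG when impossible).
    """
    n = w.shape[0]
    W = np.zeros((n, n), dtype=np.int32)
    A = np.full((n, n), NEG, dtype=np.int32)
    for span in range(min_loop + 1, n):
        for i in range(0, n - span):
            j = i + span
            # A: (i, j) paired and stacked on (i+1, j-1)
            if w[i, j] > 0 and span >= min_loop + 3 and w[i + 1, j - 1] > 0:
                inner = NEG
                if A[i + 1, j - 1] > NEG:
                    inner = A[i + 1, j - 1]
                closed = w[i + 1, j - 1] + W[i + 2, j - 2]
                if closed > inner:
                    inner = closed
                if inner > NEG:
                    A[i, j] = w[i, j] + inner
            best = W[i + 1, j]
            if W[i, j - 1] > best:
                best = W[i, j - 1]
            if A[i, j] > best:
                best = A[i, j]
            for k in range(i + 1, j):
                s = W[i, k] + W[k + 1, j]
                if s > best:
                    best = s
            W[i, j] = best
    return W, A
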