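"""Dynamic-programming kernels (numba-jitted).

Two kernels live here:

* a standard Gotoh three-state affine-gap global aligner operating on an
  arbitrary position-score matrix ``S`` (so the same kernel aligns two
  sequences or two alignment profiles), and
* a four-state variant with an extra "long deletion" state used for
  spliced-transcript alignment: deletions relative to the reference can be
  opened either as ordinary affine gaps or, at a higher opening cost but a
  near-zero per-base cost, as intron-scale gaps.

A gap of length L costs ``open + (L-1) * extend`` (both negative).  Ties are
broken deterministically: diagonal before up (gap in the second input) before
left (gap in the first input), and within a gap state opening from a match
before extending.
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG_INF = -1.0e30

# state codes shared by fill and traceback
M, X, Y, N = 0, 1, 2, 3  # match / gap-in-b (up) / gap-in-a (left) / intron


@njit(cache=True)
def gotoh_fill(S, gap_open, gap_extend):
    """Fill Gotoh matrices for global alignment over score matrix S (n x m).

    Returns (score, end_state, TM, TX, TY) where T* hold back-pointers
    (state codes) for traceback.
    """
    n, m = S.shape
    Ms = np.full((n + 1, m + 1), NEG_INF)
    Xs = np.full((n + 1, m + 1), NEG_INF)
    Ys = np.full((n + 1, m + 1), NEG_INF)
    TM = np.zeros((n + 1, m + 1), np.int8)
    TX = np.zeros((n + 1, m + 1), np.int8)
    TY = np.zeros((n + 1, m + 1), np.int8)
    Ms[0, 0] = 0.0
    for i in range(1, n + 1):
        Xs[i, 0] = gap_open + (i - 1) * gap_extend
        TX[i, 0] = M if i == 1 else X
    for j in range(1, m + 1):
        Ys[0, j] = gap_open + (j - 1) * gap_extend
        TY[0, j] = M if j == 1 else Y
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            # match state: prefer diagonal source M, then X, then Y
            best = Ms[i - 1, j - 1]
            t = M
            if Xs[i - 1, j - 1] > best:
                best = Xs[i - 1, j - 1]
                t = X
            if Ys[i - 1, j - 1] > best:
                best = Ys[i - 1, j - 1]
                t = Y
            Ms[i, j] = best + S[i - 1, j - 1]
            TM[i, j] = t
            # X: consume a[i-1] against a gap (vertical)
            best = Ms[i - 1, j] + gap_open
            t = M
            if Xs[i - 1, j] + gap_extend > best:
                best = Xs[i - 1, j] + gap_extend
                t = X
            if Ys[i - 1, j] + gap_open > best:
                best = Ys[i - 1, j] + gap_open
                t = Y
            Xs[i, j] = best
            TX[i, j] = t
            # Y: consume b[j-1] against a gap (horizontal)
            best = Ms[i, j - 1] + gap_open
            t = M
            if Ys[i, j - 1] + gap_extend > best:
                best = Ys[i, j - 1] + gap_extend
                t = Y
            if Xs[i, j - 1] + gap_open > best:
                best = Xs[i, j - 1] + gap_open
                t = X
            Ys[i, j] = best
            TY[i, j] = t
    score = Ms[n, m]
    state = M
    if Xs[n, m] > score:
        score = Xs[n, m]
        state = X
    if Ys[n, m] > score:
        score = Ys[n, m]
        state = Y
    return score, state, TM, TX, TY


def gotoh_traceback(state, TM, TX, TY):
    """Walk back-pointers; return list of moves (M=diag, X=up, Y=left)."""
    i, j = TM.shape[0] - 1, TM.shape[1] - 1
    moves: list[int] = []
    while i > 0 or j > 0:
        moves.append(state)
        if state == M:
            state = TM[i, j]
            i -= 1
            j -= 1
        elif state == X:
            state = TX[i, j]
            i -= 1
        else:
            state = TY[i, j]
            j -= 1
    moves.reverse()
    return moves


@njit(cache=True)
def intron_fill(S, gap_open, gap_extend, intron_open, intron_extend):
    """Four-state fill: Gotoh plus an intron state N (reference-side deletion
    with cheap extension).  Reference is the first axis."""
    n, m = S.shape
    Ms = np.full((n + 1, m + 1), NEG_INF)
    Xs = np.full((n + 1, m + 1), NEG_INF)
    Ys = np.full((n + 1, m + 1), NEG_INF)
    Ns = np.full((n + 1, m + 1), NEG_INF)
    TM = np.zeros((n + 1, m + 1), np.int8)
    TX = np.zeros((n + 1, m + 1), np.int8)
    TY = np.zeros((n + 1, m + 1), np.int8)
    TN = np.zeros((n + 1, m + 1), np.int8)
    Ms[0, 0] = 0.0
    for i in range(1, n + 1):
        Xs[i, 0] = gap_open + (i - 1) * gap_extend
        TX[i, 0] = M if i == 1 else X
        Ns[i, 0] = intron_open + (i - 1) * intron_extend
        TN[i, 0] = M if i == 1 else N
    for j in range(1, m + 1):
        Ys[0, j] = gap_open + (j - 1) * gap_extend
        TY[0, j] = M if j == 1 else Y
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            best = Ms[i - 1, j - 1]
            t = M
            if Xs[i - 1, j - 1] > best:
                best = Xs[i - 1, j - 1]
                t = X
            if Ys[i - 1, j - 1] > best:
                best = Ys[i - 1, j - 1]
                t = Y
            if Ns[i - 1, j - 1] > best:
                best = Ns[i - 1, j - 1]
                t = N
            Ms[i, j] = best + S[i - 1, j - 1]
            TM[i, j] = t

            best = Ms[i - 1, j] + gap_open
            t = M
            if Xs[i - 1, j] + gap_extend > best:
                best = Xs[i - 1, j] + gap_extend
                t = X
            if Ys[i - 1, j] + gap_open > best:
                best = Ys[i - 1, j] + gap_open
                t = Y
            Xs[i, j] = best
            TX[i, j] = t

            best = Ms[i, j - 1] + gap_open
            t = M
            if Ys[i, j - 1] + gap_extend > best:
                best = Ys[i, j - 1] + gap_extend
                t = Y
            if Xs[i, j - 1] + gap_open > best:
                best = Xs[i, j - 1] + gap_open
                t = X
            if Ns[i, j - 1] + gap_open > best:
                best = Ns[i, j - 1] + gap_open
                t = N
            Ys[i, j] = best
            TY[i, j] = t

            best = Ms[i - 1, j] + intron_open
            t = M
            if Ns[i - 1, j] + intron_extend > best:
                best = Ns[i - 1, j] + intron_extend
                t = N
            if Ys[i - 1, j] + intron_open > best:
                best = Ys[i - 1, j] + intron_open
                t = Y
            Ns[i, j] = best
            TN[i, j] = t
    score = Ms[n, m]
    state = M
    if Xs[n, m] > score:
        score = Xs[n, m]
        state = X
    if Ys[n, m] > score:
        score = Ys[n, m]
        state = Y
    if Ns[n, m] > score:
        score = Ns[n, m]
        state = N
    return score, state, TM, TX, TY, TN


def intron_traceback(state, TM, TX, TY, TN):
    """Return list of state codes per alignment column (reference axis first)."""
    i, j = TM.shape[0] - 1, TM.shape[1] - 1
    moves: list[int] = []
    while i > 0 or j > 0:
        moves.append(state)
        if state == M:
            state = TM[i, j]
            i -= 1
            j -= 1
        elif state == X:
            state = TX[i, j]
            i -= 1
        elif state == Y:
            state = TY[i, j]
            j -= 1
        else:
            state = TN[i, j]
            i -= 1
    moves.reverse()
    return moves
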