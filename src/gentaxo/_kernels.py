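"""Numba dynamic-programming kernels for pairwise alignment.

All kernels implement affine-gap (Gotoh three-state) alignment with a gap
of length L costing ``gap_open + L * gap_extend``.  They operate on
integer-encoded sequences and a dense substitution matrix, and return an
operation path: 0 = consume both (match column), 1 = consume query only
(gap in subject), 2 = consume subject only (gap in query).
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG = -1e30


@njit(cache=True)
def sw_affine(q, s, sub, gap_open, gap_extend):
    """Local (Smith-Waterman) alignment.

    Gap states open from the match state only (gap-gap adjacency is never
    optimal for a local alignment under standard scoring).  Returns
    (score, q_start, q_end, s_start, s_end, ops); score 0 and empty ops
    when no positive-scoring cell exists.
    """
    n = q.shape[0]
    m = s.shape[0]
    go = gap_open + gap_extend
    ge = gap_extend

    M = np.zeros((n + 1, m + 1))
    X = np.full((n + 1, m + 1), NEG)
    Y = np.full((n + 1, m + 1), NEG)
    pM = np.zeros((n + 1, m + 1), dtype=np.uint8)  # 0 fresh start, 1 M, 2 X, 3 Y
    pX = np.zeros((n + 1, m + 1), dtype=np.uint8)  # 0 open from M, 1 extend
    pY = np.zeros((n + 1, m + 1), dtype=np.uint8)

    best = 0.0
    bi = 0
    bj = 0
    for i in range(1, n + 1):
        qi = q[i - 1]
        for j in range(1, m + 1):
            xo = M[i - 1, j] - go
            xe = X[i - 1, j] - ge
            if xo >= xe:
                X[i, j] = xo
                pX[i, j] = 0
            else:
                X[i, j] = xe
                pX[i, j] = 1
            yo = M[i, j - 1] - go
            ye = Y[i, j - 1] - ge
            if yo >= ye:
                Y[i, j] = yo
                pY[i, j] = 0
            else:
                Y[i, j] = ye
                pY[i, j] = 1
            dm = M[i - 1, j - 1]
            dx = X[i - 1, j - 1]
            dy = Y[i - 1, j - 1]
            # fresh start preferred on ties (shortest alignment, same score)
            v = 0.0
            p = np.uint8(0)
            if dm > v:
                v = dm
                p = np.uint8(1)
            if dx > v:
                v = dx
                p = np.uint8(2)
            if dy > v:
                v = dy
                p = np.uint8(3)
            t = v + sub[qi, s[j - 1]]
            if t <= 0.0:
                M[i, j] = 0.0
                pM[i, j] = 0
            else:
                M[i, j] = t
                pM[i, j] = p
                if t > best:
                    best = t
                    bi = i
                    bj = j

    if best <= 0.0:
        return 0.0, 0, 0, 0, 0, np.empty(0, dtype=np.uint8)

    ops = np.empty(n + m, dtype=np.uint8)
    k = 0
    i = bi
    j = bj
    state = 1
    while True:
        if state == 1:
            p = pM[i, j]
            ops[k] = 0
            k += 1
            i -= 1
            j -= 1
            if p == 0:
                break
            state = p
        elif state == 2:
            p = pX[i, j]
            ops[k] = 1
            k += 1
            i -= 1
            state = 1 if p == 0 else 2
        else:
            p = pY[i, j]
            ops[k] = 2
            k += 1
            j -= 1
            state = 1 if p == 0 else 3
    return best, i, bi, j, bj, ops[:k][::-1].copy()


@njit(cache=True)
def nw_affine(q, s, sub, gap_open, gap_extend):
    """Global (Needleman-Wunsch) alignment end to end.

    Gap states may follow each other (needed for optimality when a
    mismatch is costlier than two gap columns).  Returns (score, ops).
    """
    n = q.shape[0]
    m = s.shape[0]
    go = gap_open + gap_extend
    ge = gap_extend

    M = np.full((n + 1, m + 1), NEG)
    X = np.full((n + 1, m + 1), NEG)
    Y = np.full((n + 1, m + 1), NEG)
    pM = np.zeros((n + 1, m + 1), dtype=np.uint8)  # predecessor state of diag move
    pX = np.zeros((n + 1, m + 1), dtype=np.uint8)  # 0 from M, 1 extend X, 2 from Y
    pY = np.zeros((n + 1, m + 1), dtype=np.uint8)  # 0 from M, 1 extend Y, 2 from X

    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = -go - (i - 1) * ge
        pX[i, 0] = 0 if i == 1 else 1
    for j in range(1, m + 1):
        Y[0, j] = -go - (j - 1) * ge
        pY[0, j] = 0 if j == 1 else 1

    for i in range(1, n + 1):
        qi = q[i - 1]
        for j in range(1, m + 1):
            xm = M[i - 1, j] - go
            xx = X[i - 1, j] - ge
            xy = Y[i - 1, j] - go
            if xm >= xx and xm >= xy:
                X[i, j] = xm
                pX[i, j] = 0
            elif xx >= xy:
                X[i, j] = xx
                pX[i, j] = 1
            else:
                X[i, j] = xy
                pX[i, j] = 2
            ym = M[i, j - 1] - go
            yy = Y[i, j - 1] - ge
            yx = X[i, j - 1] - go
            if ym >= yy and ym >= yx:
                Y[i, j] = ym
                pY[i, j] = 0
            elif yy >= yx:
                Y[i, j] = yy
                pY[i, j] = 1
            else:
                Y[i, j] = yx
                pY[i, j] = 2
            dm = M[i - 1, j - 1]
            dx = X[i - 1, j - 1]
            dy = Y[i - 1, j - 1]
            v = dm
            p = np.uint8(1)
            if dx > v:
                v = dx
                p = np.uint8(2)
            if dy > v:
                v = dy
                p = np.uint8(3)
            M[i, j] = v + sub[qi, s[j - 1]]
            pM[i, j] = p

    score = M[n, m]
    state = 1
    if X[n, m] > score:
        score = X[n, m]
        state = 2
    if Y[n, m] > score:
        score = Y[n, m]
        state = 3

    ops = np.empty(n + m, dtype=np.uint8)
    k = 0
    i = n
    j = m
    while i > 0 or j > 0:
        if state == 1:
            p = pM[i, j]
            ops[k] = 0
            k += 1
            i -= 1
            j -= 1
            state = p
        elif state == 2:
            p = pX[i, j]
            ops[k] = 1
            k += 1
            i -= 1
            state = 1 if p == 0 else (2 if p == 1 else 3)
        else:
            p = pY[i, j]
            ops[k] = 2
            k += 1
            j -= 1
            state = 1 if p == 0 else (3 if p == 1 else 2)
    return score, ops[:k][::-1].copy()


@njit(cache=True)
def nw_profile(scores, gap_open, gap_extend):
    """Global affine alignment over a precomputed column-pair score matrix.

    ``scores[i, j]`` scores aligning profile-A column i with profile-B
    column j.  Returns (score, ops); used for profile-profile merging in
    progressive multiple alignment.
    """
    n = scores.shape[0]
    m = scores.shape[1]
    go = gap_open + gap_extend
    ge = gap_extend

    M = np.full((n + 1, m + 1), NEG)
    X = np.full((n + 1, m + 1), NEG)
    Y = np.full((n + 1, m + 1), NEG)
    pM = np.zeros((n + 1, m + 1), dtype=np.uint8)
    pX = np.zeros((n + 1, m + 1), dtype=np.uint8)
    pY = np.zeros((n + 1, m + 1), dtype=np.uint8)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = -go - (i - 1) * ge
        pX[i, 0] = 0 if i == 1 else 1
    for j in range(1, m + 1):
        Y[0, j] = -go - (j - 1) * ge
        pY[0, j] = 0 if j == 1 else 1
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            xm = M[i - 1, j] - go
            xx = X[i - 1, j] - ge
            xy = Y[i - 1, j] - go
            if xm >= xx and xm >= xy:
                X[i, j] = xm
                pX[i, j] = 0
            elif xx >= xy:
                X[i, j] = xx
                pX[i, j] = 1
            else:
                X[i, j] = xy
                pX[i, j] = 2
            ym = M[i, j - 1] - go
            yy = Y[i, j - 1] - ge
            yx = X[i, j - 1] - go
            if ym >= yy and ym >= yx:
                Y[i, j] = ym
                pY[i, j] = 0
            elif yy >= yx:
                Y[i, j] = yy
                pY[i, j] = 1
            else:
                Y[i, j] = yx
                pY[i, j] = 2
            dm = M[i - 1, j - 1]
            dx = X[i - 1, j - 1]
            dy = Y[i - 1, j - 1]
            v = dm
            p = np.uint8(1)
            if dx > v:
                v = dx
                p = np.uint8(2)
            if dy > v:
                v = dy
                p = np.uint8(3)
            M[i, j] = v + scores[i - 1, j - 1]
            pM[i, j] = p

    score = M[n, m]
    state = 1
    if X[n, m] > score:
        score = X[n, m]
        state = 2
    if Y[n, m] > score:
        score = Y[n, m]
        state = 3
    ops = np.empty(n + m, dtype=np.uint8)
    k = 0
    i = n
    j = m
    while i > 0 or j > 0:
        if state == 1:
            p = pM[i, j]
            ops[k] = 0
            k += 1
            i -= 1
            j -= 1
            state = p
        elif state == 2:
            p = pX[i, j]
            ops[k] = 1
            k += 1
            i -= 1
            state = 1 if p == 0 else (2 if p == 1 else 3)
        else:
            p = pY[i, j]
            ops[k] = 2
            k += 1
            j -= 1
            state = 1 if p == 0 else (3 if p == 1 else 2)
    return score, ops[:k][::-1].copy()
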