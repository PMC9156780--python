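"""Numba inner loops for pair merging and affine-gap alignment.

Sequences are passed as uint8 arrays of ASCII codes.  Gap costs are
positive integers; a gap of length L costs ``open + L * extend`` (the
opening move is charged ``open + extend``).  State codes used in
traceback paths: 0 = M, 1 = D (gap in read, consumes reference),
2 = I (gap in reference, consumes read).
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG = np.int32(-(10**8))


@njit(cache=True)
def merge_scan(a, b, min_o, max_o):
    """Scan candidate overlaps between mate 1 ``a`` and oriented mate 2 ``b``.

    Candidate overlap length o aligns the o-suffix of ``a`` with the
    o-prefix of ``b``.  Returns (best_overlap, mismatches) for the
    candidate minimising mismatch fraction, ties going to the longest
    overlap; (-1, 0) when no candidate length fits the bounds.
    """
    la = a.size
    lb = b.size
    hi = min(max_o, la, lb)
    best_o = -1
    best_mm = 0
    for o in range(hi, min_o - 1, -1):
        mm = 0
        off = la - o
        for i in range(o):
            if a[off + i] != b[i]:
                mm += 1
        # strict improvement of mm/o keeps the longest overlap on ties
        if best_o == -1 or mm * best_o < best_mm * o:
            best_o = o
            best_mm = mm
    return best_o, best_mm


@njit(cache=True)
def semiglobal_align(read, ref, match, mismatch, orc, erc, ord_, erd):
    """Read-global, reference-local affine-gap alignment.

    The whole read must be aligned (M/I states); any reference prefix
    and suffix is free.  orc/erc open/extend gaps in the reference
    (I ops), ord_/erd open/extend gaps in the read (D ops).

    Returns (score, ref_start, path, path_len): ``path`` holds state
    codes for the optimal path in alignment order.
    """
    m = read.size
    n = ref.size
    M = np.empty((m + 1, n + 1), np.int32)
    D = np.empty((m + 1, n + 1), np.int32)
    I = np.empty((m + 1, n + 1), np.int32)
    pM = np.zeros((m + 1, n + 1), np.uint8)
    pD = np.zeros((m + 1, n + 1), np.uint8)
    pI = np.zeros((m + 1, n + 1), np.uint8)
    for j in range(n + 1):
        M[0, j] = 0
        D[0, j] = NEG
        I[0, j] = NEG
    for i in range(1, m + 1):
        M[i, 0] = NEG
        D[i, 0] = NEG
        a = M[i - 1, 0] - orc - erc
        c = I[i - 1, 0] - erc
        if a >= c:
            I[i, 0] = a
            pI[i, 0] = 0
        else:
            I[i, 0] = c
            pI[i, 0] = 2
        ri = read[i - 1]
        for j in range(1, n + 1):
            sub = match if ri == ref[j - 1] else mismatch
            # M: diagonal move, tie-break M > D > I
            a = M[i - 1, j - 1]
            b = D[i - 1, j - 1]
            c = I[i - 1, j - 1]
            if a >= b and a >= c:
                M[i, j] = a + sub
                pM[i, j] = 0
            elif b >= c:
                M[i, j] = b + sub
                pM[i, j] = 1
            else:
                M[i, j] = c + sub
                pM[i, j] = 2
            # I: consumes read base i
            a = M[i - 1, j] - orc - erc
            b = D[i - 1, j] - orc - erc
            c = I[i - 1, j] - erc
            if a >= b and a >= c:
                I[i, j] = a
                pI[i, j] = 0
            elif b >= c:
                I[i, j] = b
                pI[i, j] = 1
            else:
                I[i, j] = c
                pI[i, j] = 2
            # D: consumes reference base j
            a = M[i, j - 1] - ord_ - erd
            b = D[i, j - 1] - erd
            c = I[i, j - 1] - ord_ - erd
            if a >= b and a >= c:
                D[i, j] = a
                pD[i, j] = 0
            elif b >= c:
                D[i, j] = b
                pD[i, j] = 1
            else:
                D[i, j] = c
                pD[i, j] = 2
    # end anywhere on the reference; terminal D ops are never part of the
    # optimum (the reference suffix is free), so only M and I can end
    best = NEG
    bj = 0
    bstate = np.uint8(0)
    for j in range(n + 1):
        if M[m, j] > best:
            best = M[m, j]
            bj = j
            bstate = np.uint8(0)
        if I[m, j] > best:
            best = I[m, j]
            bj = j
            bstate = np.uint8(2)
    path = np.empty(m + n, np.uint8)
    k = 0
    i = m
    j = bj
    state = bstate
    while i > 0:
        path[k] = state
        k += 1
        if state == 0:
            nxt = pM[i, j]
            i -= 1
            j -= 1
        elif state == 1:
            nxt = pD[i, j]
            j -= 1
        else:
            nxt = pI[i, j]
            i -= 1
        state = nxt
    # drop leading D steps picked up at i == 0 (free reference prefix):
    # none are emitted because the loop stops at i == 0
    path[:k] = path[:k][::-1].copy()
    return best, j, path, k


@njit(cache=True)
def local_align(read, ref, match, mismatch, orc, erc, ord_, erd):
    """Smith-Waterman affine-gap local alignment of one mate.

    Returns (score, read_start, read_end, ref_start, ref_end, path,
    path_len) with half-open read/reference coordinates of the aligned
    segment.  score 0 means nothing aligned.
    """
    m = read.size
    n = ref.size
    M = np.empty((m + 1, n + 1), np.int32)
    D = np.empty((m + 1, n + 1), np.int32)
    I = np.empty((m + 1, n + 1), np.int32)
    pM = np.zeros((m + 1, n + 1), np.uint8)
    pD = np.zeros((m + 1, n + 1), np.uint8)
    pI = np.zeros((m + 1, n + 1), np.uint8)
    for j in range(n + 1):
        M[0, j] = 0
        D[0, j] = NEG
        I[0, j] = NEG
    best = np.int32(0)
    bi = 0
    bj = 0
    for i in range(1, m + 1):
        M[i, 0] = 0
        D[i, 0] = NEG
        I[i, 0] = NEG
        ri = read[i - 1]
        for j in range(1, n + 1):
            sub = match if ri == ref[j - 1] else mismatch
            a = M[i - 1, j - 1]
            b = D[i - 1, j - 1]
            c = I[i - 1, j - 1]
            # prefer continuing (M > D > I) over restarting
            best_cont = a
            p = np.uint8(0)
            if b > best_cont:
                best_cont = b
                p = np.uint8(1)
            if c > best_cont:
                best_cont = c
                p = np.uint8(2)
            if best_cont <= 0:
                v = sub
                p = np.uint8(3)
            else:
                v = best_cont + sub
            if v < 0:
                v = 0
                p = np.uint8(3)
            M[i, j] = v
            pM[i, j] = p
            a = M[i - 1, j] - orc - erc
            b = D[i - 1, j] - orc - erc
            c = I[i - 1, j] - erc
            if a >= b and a >= c:
                I[i, j] = a
                pI[i, j] = 0
            elif b >= c:
                I[i, j] = b
                pI[i, j] = 1
            else:
                I[i, j] = c
                pI[i, j] = 2
            a = M[i, j - 1] - ord_ - erd
            b = D[i, j - 1] - erd
            c = I[i, j - 1] - ord_ - erd
            if a >= b and a >= c:
                D[i, j] = a
                pD[i, j] = 0
            elif b >= c:
                D[i, j] = b
                pD[i, j] = 1
            else:
                D[i, j] = c
                pD[i, j] = 2
            if M[i, j] > best:
                best = M[i, j]
                bi = i
                bj = j
    path = np.empty(m + n, np.uint8)
    k = 0
    if best <= 0:
        return best, 0, 0, 0, 0, path, 0
    i = bi
    j = bj
    state = np.uint8(0)
    while True:
        path[k] = state
        k += 1
        if state == 0:
            nxt = pM[i, j]
            i -= 1
            j -= 1
            if nxt == 3:
                break
        elif state == 1:
            nxt = pD[i, j]
            j -= 1
        else:
            nxt = pI[i, j]
            i -= 1
        state = nxt
    path[:k] = path[:k][::-1].copy()
    return best, i, bi, j, bj, path, k
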