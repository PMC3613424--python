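"""Banded affine-gap local alignment kernel (Gotoh recurrences, numba-compiled).

Gap cost convention is the BLAST one: a gap of length g costs
``gap_open + g * gap_extend`` (so a length-1 gap costs open+extend).
The band restricts computed cells to diagonals ``dlo <= j - i <= dhi``
(i: 1-based query row, j: 1-based subject column); neighbours outside the
band are treated as unreachable, not as zero.
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG_INF = -(10**9)


@njit(cache=True)
def banded_local_align(q, s, sub, gap_open, gap_ext, dlo, dhi):  # pragma: no cover - numba
    """Align encoded query ``q`` vs subject ``s`` within a diagonal band.

    Returns (score, qstart, qend, sstart, send, matches, mismatches,
    gap_opens, align_len) with 1-based inclusive coordinates; score 0 means
    no positive-scoring local alignment exists in the band.
    """
    m = q.shape[0]
    n = s.shape[0]
    H = np.full((m + 1, n + 1), NEG_INF, dtype=np.int32)
    E = np.full((m + 1, n + 1), NEG_INF, dtype=np.int32)  # gap in query (left move)
    F = np.full((m + 1, n + 1), NEG_INF, dtype=np.int32)  # gap in subject (up move)
    open_cost = gap_open + gap_ext

    # Zero-floor boundary for cells adjacent to the band interior.
    for i in range(m + 1):
        jlo = i + dlo
        jhi = i + dhi
        if jlo < 0:
            jlo = 0
        if jhi > n:
            jhi = n
        for j in range(jlo, jhi + 1):
            H[i, j] = 0

    best = 0
    bi = 0
    bj = 0
    for i in range(1, m + 1):
        jlo = i + dlo
        jhi = i + dhi
        if jlo < 1:
            jlo = 1
        if jhi > n:
            jhi = n
        for j in range(jlo, jhi + 1):
            e = E[i, j - 1] - gap_ext
            if H[i, j - 1] - open_cost > e:
                e = H[i, j - 1] - open_cost
            E[i, j] = e
            f = F[i - 1, j] - gap_ext
            if H[i - 1, j] - open_cost > f:
                f = H[i - 1, j] - open_cost
            F[i, j] = f
            h = H[i - 1, j - 1] + sub[q[i - 1], s[j - 1]]
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

    if best <= 0:
        return 0, 0, 0, 0, 0, 0, 0, 0, 0

    # Traceback by re-deriving each decision from the stored matrices.
    i = bi
    j = bj
    state = 0  # 0: H, 1: E (left), 2: F (up)
    matches = 0
    mismatches = 0
    gap_opens = 0
    align_len = 0
    while True:
        if state == 0:
            if H[i, j] == 0:
                break
            if H[i, j] == E[i, j]:
                state = 1
                continue
            if H[i, j] == F[i, j]:
                state = 2
                continue
            # diagonal
            align_len += 1
            if q[i - 1] == s[j - 1]:
                matches += 1
            else:
                mismatches += 1
            i -= 1
            j -= 1
        elif state == 1:
            align_len += 1
            if E[i, j] == E[i, j - 1] - gap_ext:
                j -= 1
            else:
                gap_opens += 1
                j -= 1
                state = 0
        else:
            align_len += 1
            if F[i, j] == F[i - 1, j] - gap_ext:
                i -= 1
            else:
                gap_opens += 1
                i -= 1
                state = 0

    return best, i + 1, bi, j + 1, bj, matches, mismatches, gap_opens, align_len
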