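"""Numba Smith-Waterman / Needleman-Wunsch kernels.

All kernels work on integer-encoded sequences (see similarity.ScoringScheme).
Affine gaps follow the BLAST convention: a gap of length k costs
``gap_open + k * gap_extend``, so the first gap residue is charged
``gap_first = gap_open + gap_extend`` and every further residue ``gap_extend``.
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG = -(10**7)


@njit(cache=True)
def sw_score(a, b, sub, gap_first, gap_ext):  # pragma: no cover - jitted
    """Optimal local alignment score (Gotoh, score-only, linear memory)."""
    n = a.shape[0]
    m = b.shape[0]
    H = np.zeros(m + 1, dtype=np.int32)
    E = np.full(m + 1, NEG, dtype=np.int32)
    best = 0
    for i in range(1, n + 1):
        h_diag = 0  # H[i-1][j-1]
        h_prev = 0  # H[i][j-1]
        F = NEG
        ai = a[i - 1]
        for j in range(1, m + 1):
            e = E[j] - gap_ext
            t = H[j] - gap_first
            if t > e:
                e = t
            E[j] = e
            f = F - gap_ext
            t = h_prev - gap_first
            if t > f:
                f = t
            F = f
            h = h_diag + sub[ai, b[j - 1]]
            if e > h:
                h = e
            if f > h:
                h = f
            if h < 0:
                h = 0
            h_diag = H[j]
            H[j] = h
            h_prev = h
            if h > best:
                best = h
    return best


@njit(cache=True)
def sw_score_rows(q, subs_flat, s_bounds, sub, gap_first, gap_ext):  # pragma: no cover
    """Score one query against every subject packed in ``subs_flat``.

    ``s_bounds`` holds ``len(subjects)+1`` offsets into ``subs_flat``.
    """
    ns = s_bounds.shape[0] - 1
    out = np.empty(ns, dtype=np.int32)
    for si in range(ns):
        out[si] = sw_score(q, subs_flat[s_bounds[si]:s_bounds[si + 1]], sub, gap_first, gap_ext)
    return out


@njit(cache=True)
def sw_first_at_least(q, subs_flat, s_bounds, sub, gap_first, gap_ext, score_min):  # pragma: no cover
    """Index and score of the first subject scoring >= score_min, else (-1, -1)."""
    ns = s_bounds.shape[0] - 1
    for si in range(ns):
        s = sw_score(q, subs_flat[s_bounds[si]:s_bounds[si + 1]], sub, gap_first, gap_ext)
        if s >= score_min:
            return si, s
    return -1, np.int32(-1)


@njit(cache=True)
def nw_profile_steps(S, gap_first, gap_ext):  # pragma: no cover - jitted
    """Global affine-gap alignment over a precomputed column-score matrix.

    ``S[i, j]`` is the score for pairing column i of profile A with column j of
    profile B. Returns a step array (0 = diagonal, 1 = consume A, 2 = consume B)
    in alignment order. Ties prefer diagonal, then A-consuming steps, for
    determinism.
    """
    n, m = S.shape
    neg = -1e18
    M = np.full((n + 1, m + 1), neg)
    IA = np.full((n + 1, m + 1), neg)  # gap in B (consumes A)
    IB = np.full((n + 1, m + 1), neg)  # gap in A (consumes B)
    # backpointers: state entered from (0=M, 1=IA, 2=IB)
    bM = np.zeros((n + 1, m + 1), dtype=np.int8)
    bA = np.zeros((n + 1, m + 1), dtype=np.int8)
    bB = np.zeros((n + 1, m + 1), dtype=np.int8)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        IA[i, 0] = -gap_first - (i - 1) * gap_ext
        bA[i, 0] = 1 if i > 1 else 0
    for j in range(1, m + 1):
        IB[0, j] = -gap_first - (j - 1) * gap_ext
        bB[0, j] = 2 if j > 1 else 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            # M: from any state at (i-1, j-1)
            best = M[i - 1, j - 1]
            ptr = 0
            if IA[i - 1, j - 1] > best:
                best = IA[i - 1, j - 1]
                ptr = 1
            if IB[i - 1, j - 1] > best:
                best = IB[i - 1, j - 1]
                ptr = 2
            M[i, j] = best + S[i - 1, j - 1]
            bM[i, j] = ptr
            # IA: gap in B
            openv = M[i - 1, j] - gap_first
            extv = IA[i - 1, j] - gap_ext
            if openv >= extv:
                IA[i, j] = openv
                bA[i, j] = 0
            else:
                IA[i, j] = extv
                bA[i, j] = 1
            # IB: gap in A
            openv = M[i, j - 1] - gap_first
            extv = IB[i, j - 1] - gap_ext
            if openv >= extv:
                IB[i, j] = openv
                bB[i, j] = 0
            else:
                IB[i, j] = extv
                bB[i, j] = 2
    # traceback
    state = 0
    best = M[n, m]
    if IA[n, m] > best:
        best = IA[n, m]
        state = 1
    if IB[n, m] > best:
        state = 2
    steps = np.empty(n + m, dtype=np.int8)
    k = 0
    i, j = n, m
    while i > 0 or j > 0:
        if state == 0:
            steps[k] = 0
            prev = bM[i, j]
            i -= 1
            j -= 1
        elif state == 1:
            steps[k] = 1
            prev = bA[i, j]
            i -= 1
        else:
            steps[k] = 2
            prev = bB[i, j]
            j -= 1
        state = prev
        k += 1
    return steps[:k][::-1].copy()
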