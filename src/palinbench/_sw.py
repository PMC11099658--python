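"""Numba kernels for affine-gap Smith–Waterman local alignment (Gotoh).

Gap cost convention: a gap of length g costs open + (g−1)·extend, i.e. the
open penalty is charged on the first gapped position, matching blastp's
reported "open −11 / extend −1" semantics.  All costs are passed as positive
magnitudes.  Scores are integer matrix units (half-bits for BLOSUM62).
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG = np.int64(-(10**15))


@njit(cache=True)
def sw_score(a, b, sub, gap_open, gap_extend):
    """Best local-alignment score only (O(min-dim) memory)."""
    n, m = len(a), len(b)
    H = np.zeros(m + 1, dtype=np.int64)
    E = np.full(m + 1, NEG, dtype=np.int64)
    best = np.int64(0)
    for i in range(1, n + 1):
        diag = np.int64(0)  # H[i-1][0]
        F = NEG
        for j in range(1, m + 1):
            # E: gap in a (consumes b[j-1]); F: gap in b (consumes a[i-1])
            e = max(H[j] - gap_open, E[j] - gap_extend)
            f = max(H[j - 1] - gap_open, F - gap_extend)
            h = diag + sub[a[i - 1], b[j - 1]]
            if e > h:
                h = e
            if f > h:
                h = f
            if h < 0:
                h = 0
            diag = H[j]
            H[j] = h
            E[j] = e
            F = f
            if h > best:
                best = h
    return best


@njit(cache=True)
def sw_matrices(a, b, sub, gap_open, gap_extend):
    """Full H/E/F matrices for traceback, plus the argmax cell.

    Ties for the best cell resolve to the smallest (i, j) in row-major order.
    """
    n, m = len(a), len(b)
    H = np.zeros((n + 1, m + 1), dtype=np.int64)
    E = np.full((n + 1, m + 1), NEG, dtype=np.int64)
    F = np.full((n + 1, m + 1), NEG, dtype=np.int64)
    best = np.int64(0)
    bi = 0
    bj = 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            e = max(H[i, j - 1] - gap_open, E[i, j - 1] - gap_extend)
            f = max(H[i - 1, j] - gap_open, F[i - 1, j] - gap_extend)
            h = H[i - 1, j - 1] + sub[a[i - 1], b[j - 1]]
            if e > h:
                h = e
            if f > h:
                h = f
            if h < 0:
                h = 0
            H[i, j] = h
            E[i, j] = e
            F[i, j] = f
            if h > best:
                best = h
                bi = i
                bj = j
    return H, E, F, best, bi, bj
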