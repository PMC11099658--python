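"""Exact maximal-palindrome detection (Manacher's algorithm).

A palindrome here is a substring that reads identically forwards and
backwards (LIWMMWIL) — not the genomics reverse-complement usage.  Manacher's
algorithm finds, in O(L), the maximal palindromic substring centred at every
residue and at every inter-residue gap (2L−1 centres, covering odd and even
lengths).

Masked residues match nothing, including themselves: a palindrome can never
cross a masked position, and the maximal palindrome centred on one has length
0.  (Hard-masking therefore strictly shortens palindromes, which is the point
of masking before measuring them.)  Implementation detail: each masked
position is encoded as a unique symbol before the scan.

Intervals are 0-based half-open throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .records import SequenceRecord, encode


@dataclass
class PalindromeAnnotation:
    """Maximal palindromes of one sequence, one interval per centre."""

    sequence_id: str
    maximal_palindromes: list[tuple[int, int]]
    lps_length: int
    lps_interval: tuple[int, int]


def _manacher_radii(codes: np.ndarray) -> np.ndarray:
    """Radii of maximal palindromes in the separator-augmented array.

    t has length 2L+1: separators at even indices, residues at odd indices.
    rad[c] is the largest r with t[c-r:c+r+1] a palindrome.
    """
    L = len(codes)
    SEP = np.int64(-1)
    t = np.full(2 * L + 1, SEP, dtype=np.int64)
    t[1::2] = codes
    n = len(t)
    rad = np.zeros(n, dtype=np.int64)
    center = right = 0
    for i in range(n):
        if i < right:
            rad[i] = min(right - i, rad[2 * center - i])
        while i - rad[i] - 1 >= 0 and i + rad[i] + 1 < n and t[i - rad[i] - 1] == t[i + rad[i] + 1]:
            rad[i] += 1
        if i + rad[i] > right:
            center, right = i, i + rad[i]
    return rad


def maximal_palindromes(seq: SequenceRecord) -> PalindromeAnnotation:
    """All maximal palindromes of *seq*, plus its LPS length and interval."""
    L = len(seq)
    codes = encode(seq, masked_unique=True)
    rad = _manacher_radii(codes)
    intervals: list[tuple[int, int]] = []
    # odd centres: residue i sits at augmented index 2i+1; palindrome length rad
    for i in range(L):
        if seq.mask[i]:
            intervals.append((i, i))
            continue
        r = int(rad[2 * i + 1]) // 2  # residues on each side
        intervals.append((i - r, i + r + 1))
    # even centres: gap between residues i-1 and i sits at augmented index 2i
    for i in range(1, L):
        r = (int(rad[2 * i]) + 1) // 2
        intervals.append((i - r, i + r))
    best = max(intervals, key=lambda iv: iv[1] - iv[0], default=(0, 0))
    return PalindromeAnnotation(seq.id, intervals, best[1] - best[0], best)


def lps_length(seq: SequenceRecord) -> int:
    return maximal_palindromes(seq).lps_length


def mean_lps_by_length(
    seqs: list[SequenceRecord], bins: np.ndarray | list[float]
) -> pd.DataFrame:
    """Mean LPS length per sequence-length bin.

    *bins* are length-bin edges (half-open [lo, hi) per bin).  Empty bins are
    emitted with count 0 and NaN mean.
    """
    if not seqs:
        raise ValueError("need at least one sequence")
    edges = np.asarray(bins, dtype=float)
    lengths = np.array([len(s) for s in seqs])
    lps = np.array([lps_length(s) for s in seqs])
    which = np.digitize(lengths, edges) - 1
    rows = []
    for b in range(len(edges) - 1):
        sel = which == b
        rows.append(
            {
                "bin_lo": edges[b],
                "bin_hi": edges[b + 1],
                "mean_lps": float(lps[sel].mean()) if sel.any() else np.nan,
                "count": int(sel.sum()),
            }
        )
    return pd.DataFrame(rows)
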