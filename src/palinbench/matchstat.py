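"""Local alignment scoring and longest-common-substring machinery.

Two routes to exact/approximate matching are provided:

* :func:`sw_align` — affine-gap Smith–Waterman with BLAST's default
  parameterisation (BLOSUM62 half-bit matrix, gap open −11 / extend −1,
  where a length-g gap costs 11 + (g−1)·1).  An ``exact_only`` scheme sets
  all mismatch and gap costs to a huge negative number, which makes SW report
  exactly the length of the longest common substring — the paper-trail
  bridge between alignment scores and LCS theory.
* :func:`lcs` — linear-time longest common substring via a suffix automaton,
  used for the large LCS surveys and cross-checked against exact-only SW.

The mask symbol ``X`` is scored with BLOSUM62's own X row (mostly −1), the
behaviour blastp exhibits on hard-masked input.  This deliberately differs
from the palindrome module, where a masked residue matches nothing at all.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio.Align import substitution_matrices

from .records import ALPHABETS, MASK_SYMBOL, SequenceRecord
from . import _sw

BIG = 10**12


@dataclass
class AlignmentResult:
    query_id: str
    target_id: str
    score: int
    identity_fraction: float
    query_interval: tuple[int, int]
    target_interval: tuple[int, int]
    n_gap_columns: int


class ScoringScheme:
    """Substitution matrix plus affine gap costs.

    mode ``local_affine`` is standard SW; ``exact_only`` is match=+1 with
    effectively infinite mismatch/gap penalties (SW then performs exact
    matching and its score equals the LCS length).
    """

    def __init__(self, matrix, symbols: str, gap_open: int = 11, gap_extend: int = 1,
                 mode: str = "local_affine", alphabet: str | None = None):
        if mode not in ("local_affine", "exact_only"):
            raise ValueError(f"unknown mode {mode!r}")
        self.symbols = symbols
        self.matrix = np.asarray(matrix, dtype=np.int64)
        self.gap_open = int(gap_open)
        self.gap_extend = int(gap_extend)
        self.mode = mode
        self.alphabet = alphabet
        self._lut = np.full(128, -1, dtype=np.int64)
        for i, c in enumerate(symbols):
            self._lut[ord(c)] = i

    @classmethod
    def blosum62(cls) -> "ScoringScheme":
        return cls._from_named("BLOSUM62")

    @classmethod
    def blosum90(cls) -> "ScoringScheme":
        return cls._from_named("BLOSUM90")

    @classmethod
    def _from_named(cls, name: str) -> "ScoringScheme":
        arr = substitution_matrices.load(name)
        symbols = ALPHABETS["protein20"] + MASK_SYMBOL["protein20"]
        idx = [arr.alphabet.index(c) for c in symbols]
        M = np.array(arr)[np.ix_(idx, idx)].astype(np.int64)
        return cls(M, symbols, 11, 1, "local_affine", "protein20")

    @classmethod
    def from_file(cls, path, alphabet: str = "protein20") -> "ScoringScheme":
        """NCBI matrix text format."""
        arr = substitution_matrices.read(str(path))
        symbols = "".join(c for c in ALPHABETS[alphabet] + MASK_SYMBOL[alphabet]
                          if c in arr.alphabet)
        idx = [arr.alphabet.index(c) for c in symbols]
        M = np.array(arr)[np.ix_(idx, idx)].astype(np.int64)
        return cls(M, symbols, 11, 1, "local_affine", alphabet)

    @classmethod
    def exact(cls, alphabet: str = "protein20") -> "ScoringScheme":
        letters = ALPHABETS[alphabet] + MASK_SYMBOL[alphabet]
        s = len(letters)
        M = np.full((s, s), -BIG, dtype=np.int64)
        np.fill_diagonal(M, 1)
        return cls(M, letters, BIG, BIG, "exact_only", alphabet)

    @classmethod
    def dna(cls, match: int = 2, mismatch: int = -3, gap_open: int = 5,
            gap_extend: int = 2) -> "ScoringScheme":
        """Simple DNA scheme (blastn-like megablast defaults)."""
        letters = ALPHABETS["dna4"] + MASK_SYMBOL["dna4"]
        s = len(letters)
        M = np.full((s, s), mismatch, dtype=np.int64)
        np.fill_diagonal(M, match)
        M[-1, :] = M[:, -1] = mismatch  # N never rewarded
        return cls(M, letters, gap_open, gap_extend, "local_affine", "dna4")

    def encode(self, seq: SequenceRecord) -> np.ndarray:
        if self.alphabet is not None and seq.alphabet != self.alphabet:
            raise ValueError(
                f"sequence {seq.id!r} has alphabet {seq.alphabet}, scheme expects {self.alphabet}"
            )
        codes = self._lut[np.frombuffer(seq.residues.encode(), dtype=np.uint8)]
        if (codes < 0).any():
            pos = int(np.nonzero(codes < 0)[0][0])
            raise ValueError(f"symbol {seq.residues[pos]!r} not covered by scoring scheme")
        return codes


def sw_score(q: SequenceRecord, t: SequenceRecord, scheme: ScoringScheme) -> int:
    """Optimal local alignment score only (fast path, O(m) memory)."""
    a, b = scheme.encode(q), scheme.encode(t)
    return int(_sw.sw_score(a, b, scheme.matrix, scheme.gap_open, scheme.gap_extend))


def sw_align(q: SequenceRecord, t: SequenceRecord, scheme: ScoringScheme) -> AlignmentResult:
    """Optimal local alignment with traceback.

    Traceback ties break deterministically (diagonal > up > left), which can
    affect the reported intervals but never the score.
    """
    a, b = scheme.encode(q), scheme.encode(t)
    H, E, F, best, bi, bj = _sw.sw_matrices(a, b, scheme.matrix, scheme.gap_open, scheme.gap_extend)
    if best <= 0:
        return AlignmentResult(q.id, t.id, 0, 0.0, (0, 0), (0, 0), 0)
    i, j = bi, bj
    state = "H"
    matches = columns = gaps = 0
    go, ge = scheme.gap_open, scheme.gap_extend
    while True:
        if state == "H":
            h = H[i, j]
            if h == 0:
                break
            if h == H[i - 1, j - 1] + scheme.matrix[a[i - 1], b[j - 1]]:
                columns += 1
                if a[i - 1] == b[j - 1]:
                    matches += 1
                i, j = i - 1, j - 1
            elif h == F[i, j]:
                state = "F"
            else:
                state = "E"
        elif state == "F":  # gap in target: consume a[i-1]
            columns += 1
            gaps += 1
            if F[i, j] == H[i - 1, j] - go:
                state = "H"
            i -= 1
        else:  # state E, gap in query: consume b[j-1]
            columns += 1
            gaps += 1
            if E[i, j] == H[i, j - 1] - go:
                state = "H"
            j -= 1
    return AlignmentResult(
        q.id, t.id, int(best),
        matches / columns if columns else 0.0,
        (int(i), int(bi)), (int(j), int(bj)), gaps,
    )


# ---------------------------------------------------------------------------
# Longest common substring via suffix automaton

class _SuffixAutomaton:
    """Suffix automaton over arbitrary hashable symbols (dict transitions)."""

    __slots__ = ("link", "length", "trans", "endpos", "last")

    def __init__(self, symbols: Sequence) -> None:
        self.link = [-1]
        self.length = [0]
        self.trans: list[dict] = [{}]
        self.endpos = [-1]
        self.last = 0
        for pos, c in enumerate(symbols):
            self._extend(c, pos)

    def _extend(self, c, pos: int) -> None:
        cur = len(self.length)
        self.length.append(self.length[self.last] + 1)
        self.link.append(-1)
        self.trans.append({})
        self.endpos.append(pos)
        p = self.last
        while p != -1 and c not in self.trans[p]:
            self.trans[p][c] = cur
            p = self.link[p]
        if p == -1:
            self.link[cur] = 0
        else:
            q = self.trans[p][c]
            if self.length[p] + 1 == self.length[q]:
                self.link[cur] = q
            else:
                clone = len(self.length)
                self.length.append(self.length[p] + 1)
                self.link.append(self.link[q])
                self.trans.append(dict(self.trans[q]))
                self.endpos.append(self.endpos[q])
                while p != -1 and self.trans[p].get(c) == q:
                    self.trans[p][c] = clone
                    p = self.link[p]
                self.link[q] = clone
                self.link[cur] = clone
        self.last = cur


def lcs(a: SequenceRecord, b: SequenceRecord) -> tuple[int, tuple[int, int], tuple[int, int]]:
    """Longest exact common substring of *a* and *b*.

    Returns ``(length, a_interval, b_interval)`` with 0-based half-open
    intervals (one witness occurrence each; empty intervals for length 0).
    Masked residues match nothing, including each other, mirroring the
    palindrome module so that ``lcs(s, reverse(s))`` equals the LPS length of
    ``s`` even on masked input.
    """
    from .records import encode as _encode

    ca = _encode(a, masked_unique=True)
    # offset b's unique mask codes so they can't collide with a's
    cb = _encode(b, masked_unique=True)
    cb[cb < -1] -= len(ca) + 2
    sam = _SuffixAutomaton(ca.tolist())
    best = 0
    best_b_end = -1
    best_state = 0
    v, ln = 0, 0
    for j, c in enumerate(cb.tolist()):
        while v != 0 and c not in sam.trans[v]:
            v = sam.link[v]
            ln = sam.length[v]
        if c in sam.trans[v]:
            v = sam.trans[v][c]
            ln += 1
        else:
            v, ln = 0, 0
        if ln > best:
            best = ln
            best_b_end = j
            best_state = v
    if best == 0:
        return 0, (0, 0), (0, 0)
    a_end = sam.endpos[best_state]
    return best, (a_end - best + 1, a_end + 1), (best_b_end - best + 1, best_b_end + 1)


def score_by_length(
    pairs: Iterable[tuple[SequenceRecord, SequenceRecord]],
    scheme: ScoringScheme,
    bins: np.ndarray | list[float],
) -> pd.DataFrame:
    """Mean SW score per length bin.

    The bin key for a pair is the common length when query and target lengths
    are equal, else the geometric mean √(|q|·|t|).
    """
    keys, scores = [], []
    for q, t in pairs:
        lq, lt = len(q), len(t)
        keys.append(float(lq) if lq == lt else float(np.sqrt(lq * lt)))
        scores.append(sw_score(q, t, scheme))
    if not keys:
        raise ValueError("need at least one pair")
    edges = np.asarray(bins, dtype=float)
    which = np.digitize(keys, edges) - 1
    scores_arr = np.array(scores, dtype=float)
    rows = []
    for bnum in range(len(edges) - 1):
        sel = which == bnum
        rows.append({
            "bin_lo": edges[bnum], "bin_hi": edges[bnum + 1],
            "mean_score": float(scores_arr[sel].mean()) if sel.any() else np.nan,
            "count": int(sel.sum()),
        })
    return pd.DataFrame(rows)
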