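"""Sequence-level transformations: shuffle, reverse, and their composition.

``reverse`` is true character reversal — never reverse complementation, even
for DNA.  ``shuffle`` draws a uniformly random permutation (Fisher–Yates, via
numpy's permutation) of the residues; mask flags travel with their residues.
A useful bridge relation follows from these definitions: every palindromic
substring of ``s`` is a common substring of ``s`` and ``reverse(s)``, so
``LCS(s, reverse(s)) >= LPS(s)``.  (Equality does not always hold — the LCS
can instead be a *reversed repeat*, a word occurring both forwards and
backwards at different positions, as in ``CADEAC`` where ``CA``/``AC`` beat
the trivial length-1 palindromes.)
"""

from __future__ import annotations

import numpy as np

from .records import SequenceRecord


def shuffle(seq: SequenceRecord, seed: int) -> SequenceRecord:
    """Uniformly random permutation of the residues (composition preserved)."""
    rng = np.random.default_rng((seed, 11))
    chars = np.array(list(seq.residues))
    perm = rng.permutation(len(chars))
    return SequenceRecord(seq.tagged("shuf"), seq.alphabet, "".join(chars[perm]))


def reverse(seq: SequenceRecord) -> SequenceRecord:
    """Reverse residue order (no complementation); an involution."""
    new_id = seq.id[:-4] if seq.id.endswith("|rev") else seq.tagged("rev")
    return SequenceRecord(new_id, seq.alphabet, seq.residues[::-1])


def shufrev(seq: SequenceRecord, seed: int) -> SequenceRecord:
    """Reverse of the shuffled sequence (the `shufrev` pairing partner)."""
    sh = shuffle(seq, seed)
    return SequenceRecord(seq.tagged("shufrev"), seq.alphabet, sh.residues[::-1])
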