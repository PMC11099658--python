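"""Sequence records, alphabets and FASTA I/O.

A :class:`SequenceRecord` is the package-wide container for one named
sequence.  Two alphabets are supported: the 20 canonical amino acids
(``protein20``, mask symbol ``X``) and the four DNA bases (``dna4``, mask
symbol ``N``).  Ambiguity codes (B, Z, U, O, ...) are rejected on input with
a clear error because every statistical model in the package is defined over
the canonical letters.  The mask flag is kept in lock-step with the mask
symbol: position ``i`` is flagged masked iff ``residues[i]`` is the mask
symbol.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

PROTEIN = "protein20"
DNA = "dna4"

ALPHABETS: dict[str, str] = {
    PROTEIN: "ACDEFGHIKLMNPQRSTVWY",
    DNA: "ACGT",
}
MASK_SYMBOL: dict[str, str] = {PROTEIN: "X", DNA: "N"}

_AMBIGUITY = {
    PROTEIN: set("BZUOJ*"),
    DNA: set("RYSWKMBDHV"),
}


@dataclass
class SequenceRecord:
    """One named sequence with an alphabet tag and per-position mask flags."""

    id: str
    alphabet: str
    residues: str
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.alphabet not in ALPHABETS:
            raise ValueError(f"unknown alphabet {self.alphabet!r}")
        if len(self.residues) < 1:
            raise ValueError("sequence must have length >= 1")
        letters = set(ALPHABETS[self.alphabet])
        msym = MASK_SYMBOL[self.alphabet]
        bad = {c for c in self.residues if c not in letters and c != msym}
        if bad:
            amb = bad & _AMBIGUITY[self.alphabet]
            if amb:
                raise ValueError(
                    f"sequence {self.id!r} contains ambiguity code(s) "
                    f"{sorted(amb)}; only the {len(letters)} canonical "
                    f"{self.alphabet} letters (plus mask symbol {msym!r}) are supported"
                )
            raise ValueError(f"sequence {self.id!r} contains invalid symbol(s) {sorted(bad)}")
        derived = np.frombuffer(self.residues.encode(), dtype="S1") == msym.encode()
        if self.mask is None:
            self.mask = derived
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if len(self.mask) != len(self.residues):
                raise ValueError("mask length does not match sequence length")
            if not np.array_equal(self.mask, derived):
                raise ValueError("mask flags must be true exactly at mask-symbol positions")

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def masked_fraction(self) -> float:
        return float(self.mask.mean())

    def with_residues(self, residues: str, id: str | None = None) -> "SequenceRecord":
        return SequenceRecord(id or self.id, self.alphabet, residues)

    def tagged(self, transform: str) -> str:
        """Provenance id suffix: ``origid|transform``."""
        return f"{self.id}|{transform}"


def encode(rec: SequenceRecord, masked_unique: bool = False) -> np.ndarray:
    """Map residues to integer codes 0..s-1; mask symbol becomes -1, or a
    unique negative id per position when *masked_unique* (so masked residues
    can never match anything, including themselves)."""
    letters = ALPHABETS[rec.alphabet]
    lut = np.full(128, -1, dtype=np.int64)
    for i, c in enumerate(letters):
        lut[ord(c)] = i
    codes = lut[np.frombuffer(rec.residues.encode(), dtype=np.uint8)]
    if masked_unique:
        idx = np.nonzero(rec.mask)[0]
        codes[idx] = -(idx + 2)
    return codes


def read_fasta(path, alphabet: str, softmask_to_hard: bool = False) -> list[SequenceRecord]:
    """Read a multi-FASTA file.  Lowercase letters are soft-mask annotation;
    with *softmask_to_hard* they are converted to the hard-mask symbol,
    otherwise uppercased."""
    msym = MASK_SYMBOL[alphabet]
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        s = str(rec.seq)
        if softmask_to_hard:
            s = "".join(msym if c.islower() else c for c in s)
        out.append(SequenceRecord(rec.id, alphabet, s.upper()))
    return out


def write_fasta(records: list[SequenceRecord], path) -> None:
    """Write standard multi-FASTA wrapped at 60 columns."""
    bio = [SeqRecord(Seq(r.residues), id=r.id, description="") for r in records]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=60)
        writer.write_file(bio)
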