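"""Synthetic sequence generation.

Generates the inputs every downstream analysis assumes: i.i.d. random
sequences over a stated residue composition and length distribution, plus
sequences with embedded (possibly degenerate) tandem repeats.  Defaults mirror
the study conditions used throughout the package: uniform letter frequencies
(so the match amplitude λ₂ equals 1/s exactly) and lengths uniform on
[280, 320], the slice used for the score-distribution analyses.

Randomness contract: one top-level integer seed; a substream is derived per
sequence index with ``np.random.default_rng((seed, index))``, so generating
n+1 sequences reproduces the first n byte-for-byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .records import ALPHABETS, DNA, PROTEIN, SequenceRecord

# Swiss-Prot-wide amino acid composition (UniProtKB statistics), provided for
# realism; theory-anchored analyses use the uniform default.
SWISSPROT_LIKE = {
    "A": 0.0825, "C": 0.0138, "D": 0.0546, "E": 0.0672, "F": 0.0386,
    "G": 0.0707, "H": 0.0227, "I": 0.0591, "K": 0.0580, "L": 0.0965,
    "M": 0.0241, "N": 0.0406, "P": 0.0474, "Q": 0.0393, "R": 0.0553,
    "S": 0.0664, "T": 0.0535, "V": 0.0686, "W": 0.0110, "Y": 0.0292,
}


@dataclass
class CompositionSpec:
    """Letter-frequency and length model for random sequence generation.

    length_sampler is one of ``("fixed", n)``, ``("uniform_range", lo, hi)``
    (inclusive bounds) or ``("empirical_list", [l1, l2, ...])`` (sampled with
    replacement).
    """

    alphabet: str
    letter_probabilities: np.ndarray = field(default=None)  # type: ignore[assignment]
    length_sampler: tuple = ("uniform_range", 280, 320)

    def __post_init__(self) -> None:
        s = len(ALPHABETS[self.alphabet])
        if self.letter_probabilities is None:
            self.letter_probabilities = np.full(s, 1.0 / s)
        self.letter_probabilities = np.asarray(self.letter_probabilities, dtype=float)
        p = self.letter_probabilities
        if p.shape != (s,):
            raise ValueError(f"letter_probabilities must have length {s}")
        if (p < 0).any() or abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("letter_probabilities must be nonnegative and sum to 1")
        kind = self.length_sampler[0]
        if kind not in ("fixed", "uniform_range", "empirical_list"):
            raise ValueError(f"unknown length sampler {kind!r}")
        if kind == "uniform_range" and self.length_sampler[1] > self.length_sampler[2]:
            raise ValueError("uniform_range bounds out of order")

    @classmethod
    def uniform_protein(cls, length_sampler=("uniform_range", 280, 320)) -> "CompositionSpec":
        return cls(PROTEIN, None, length_sampler)

    @classmethod
    def uniform_dna(cls, length_sampler=("uniform_range", 280, 320)) -> "CompositionSpec":
        return cls(DNA, None, length_sampler)

    @classmethod
    def swissprot_like(cls, length_sampler=("uniform_range", 280, 320)) -> "CompositionSpec":
        probs = np.array([SWISSPROT_LIKE[a] for a in ALPHABETS[PROTEIN]])
        return cls(PROTEIN, probs / probs.sum(), length_sampler)

    def sample_length(self, rng: np.random.Generator) -> int:
        kind = self.length_sampler[0]
        if kind == "fixed":
            return int(self.length_sampler[1])
        if kind == "uniform_range":
            lo, hi = self.length_sampler[1], self.length_sampler[2]
            return int(rng.integers(lo, hi + 1))
        lengths = self.length_sampler[1]
        return int(lengths[rng.integers(0, len(lengths))])


@dataclass
class RepeatSpec:
    """A tandem array to embed: *unit* repeated *copies* times, each position
    independently substituted at *per_position_mutation_rate*.  If *unit* is
    None a random unit of *unit_length* letters is drawn."""

    unit_length: int = 2
    copies: int = 4
    per_position_mutation_rate: float = 0.0
    insertion_position: tuple = ("random",)  # or ("fixed", index)
    unit: str | None = None

    def __post_init__(self) -> None:
        if self.unit is not None:
            self.unit_length = len(self.unit)
        if self.unit_length < 1 or self.copies < 2:
            raise ValueError("need unit_length >= 1 and copies >= 2")
        if not 0.0 <= self.per_position_mutation_rate <= 1.0:
            raise ValueError("mutation rate must be in [0, 1]")


def generate_random(spec: CompositionSpec, n: int, seed: int) -> list[SequenceRecord]:
    """Sample *n* i.i.d. sequences from *spec*; reproducible given *seed*."""
    if n < 1:
        raise ValueError("n must be >= 1")
    letters = np.array(list(ALPHABETS[spec.alphabet]))
    out = []
    for i in range(n):
        rng = np.random.default_rng((seed, i))
        length = spec.sample_length(rng)
        res = "".join(rng.choice(letters, size=length, p=spec.letter_probabilities))
        out.append(SequenceRecord(f"seq{i:05d}", spec.alphabet, res))
    return out


def insert_repeat(seq: SequenceRecord, repeat: RepeatSpec, seed: int) -> SequenceRecord:
    """Overwrite a window of *seq* with a (possibly degenerate) tandem array.

    Length is unchanged; substitutions always change the letter, so at rate 1
    no array position equals the clean array.
    """
    rng = np.random.default_rng((seed, 7151))
    letters = ALPHABETS[seq.alphabet]
    unit = repeat.unit or "".join(rng.choice(list(letters), size=repeat.unit_length))
    block = list(unit * repeat.copies)
    L, B = len(seq), len(block)
    if B > L:
        raise ValueError(f"repeat block (length {B}) longer than sequence (length {L})")
    for k in range(B):
        if rng.random() < repeat.per_position_mutation_rate:
            alt = [c for c in letters if c != block[k]]
            block[k] = alt[rng.integers(0, len(alt))]
    if repeat.insertion_position[0] == "fixed":
        start = int(repeat.insertion_position[1])
        if start < 0 or start + B > L:
            raise ValueError("fixed insertion position out of range")
    else:
        start = int(rng.integers(0, L - B + 1))
    res = seq.residues[:start] + "".join(block) + seq.residues[start + B:]
    return SequenceRecord(seq.tagged("rep"), seq.alphabet, res)
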