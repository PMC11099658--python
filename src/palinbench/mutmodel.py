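"""Conditional substitution models derived from log-odds matrices.

A log-odds matrix ``s_ab`` (half-bit integers for the BLOSUM family) implies
a joint substitution distribution: there is a unique scale ``λ* > 0`` such
that ``q_ab = p(a) p(b) exp(λ* s_ab)`` is a proper joint distribution whose
marginals are the backgrounds ``p``.  Marginal consistency reduces to the
linear system ``exp(λ* S) p = 1`` with the normalisation ``Σ p = 1`` pinning
λ*, so the inversion is a one-dimensional root find wrapped around a linear
solve.  The conditional rows ``p(b|a) = q_ab / p(a)`` are the per-residue
mutation distributions used to simulate diverged homologs.

The *mean self-emission* of a model — the unweighted mean over the alphabet
of ``p(a|a)`` — controls the expected percent identity between a sequence and
its mutated copy.  ``tune_self_emission`` raises it by scaling every
off-diagonal conditional entry by one global factor γ (preserving all
relative mutation preferences), which is how the graded 50–90 %-identity
variants are built.

Because the published BLOSUM matrices are rounded to integer half-bits, the
recovered ``q`` is itself an approximation of the matrix's original target
frequencies; diagonal summaries can differ from values computed on unrounded
frequency data by several tenths of a percentage point.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from Bio.Align import substitution_matrices
from scipy.optimize import brentq

from .records import ALPHABETS, PROTEIN, SequenceRecord

PROTEIN_LETTERS = ALPHABETS[PROTEIN]


class DerivationError(ValueError):
    """Raised when a matrix admits no consistent implied-frequency solution."""


@dataclass
class ConditionalSubstitutionModel:
    """Background frequencies p(a) and row-stochastic conditionals p(b|a)."""

    alphabet: str  # the letters, in row/column order
    background: np.ndarray
    conditional: np.ndarray

    def __post_init__(self) -> None:
        s = len(self.alphabet)
        self.background = np.asarray(self.background, dtype=float)
        self.conditional = np.asarray(self.conditional, dtype=float)
        if self.background.shape != (s,) or self.conditional.shape != (s, s):
            raise ValueError("shape mismatch between alphabet and model arrays")
        if (self.conditional < -1e-12).any():
            raise ValueError("conditional entries must be nonnegative")
        rows = self.conditional.sum(axis=1)
        if np.abs(rows - 1.0).max() > 1e-9:
            raise ValueError("conditional rows must sum to 1 within 1e-9")

    @property
    def mean_self_emission(self) -> float:
        """Unweighted mean over the alphabet of p(a|a)."""
        return float(np.diag(self.conditional).mean())

    @property
    def weighted_self_emission(self) -> float:
        """Background-weighted mean Σ_a p(a)·p(a|a) — the expected identity of
        a mutated copy when the input composition equals the background."""
        return float(np.dot(self.background, np.diag(self.conditional)))

    @property
    def joint(self) -> np.ndarray:
        return self.background[:, None] * self.conditional

    def to_json(self, path) -> None:
        payload = {
            "alphabet": self.alphabet,
            "background": self.background.tolist(),
            "conditional": self.conditional.tolist(),
            "mean_self_emission": self.mean_self_emission,
            "weighted_self_emission": self.weighted_self_emission,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "ConditionalSubstitutionModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(d["alphabet"], np.array(d["background"]), np.array(d["conditional"]))


def load_logodds(matrix) -> tuple[np.ndarray, str]:
    """Accept a matrix name ("BLOSUM90"), an NCBI-format matrix file path, a
    Bio substitution_matrices Array, or a plain square ndarray (rows ordered
    like the canonical protein letters).  Returns (S, letters) restricted to
    the 20 canonical amino acids."""
    if isinstance(matrix, str) and matrix.upper() in substitution_matrices.load():
        arr = substitution_matrices.load(matrix.upper())
    elif isinstance(matrix, str):
        arr = substitution_matrices.read(matrix)
    elif isinstance(matrix, substitution_matrices.Array):
        arr = matrix
    else:
        S = np.asarray(matrix, dtype=float)
        if S.ndim != 2 or S.shape[0] != S.shape[1]:
            raise ValueError("score matrix must be square")
        letters = PROTEIN_LETTERS[: S.shape[0]]
        return S, letters
    letters = "".join(c for c in PROTEIN_LETTERS if c in arr.alphabet)
    idx = [arr.alphabet.index(c) for c in letters]
    S = np.array(arr)[np.ix_(idx, idx)]
    return S, letters


def derive_from_logodds(matrix, letters: str | None = None) -> ConditionalSubstitutionModel:
    """Invert a symmetric log-odds matrix to its implied conditional model.

    Solves for the unique λ* > 0 with ``exp(λ* S) p = 1`` and ``Σ p = 1``,
    then forms ``q = p pᵀ ∘ exp(λ* S)`` and ``p(b|a) = q_ab / p(a)``.
    Raises :class:`DerivationError` when no valid scale exists (asymmetric or
    otherwise inconsistent matrices).
    """
    if letters is None:
        S, letters = load_logodds(matrix)
    else:
        S = np.asarray(matrix, dtype=float)
    if not np.allclose(S, S.T):
        raise DerivationError("log-odds matrix must be symmetric")

    def background(lam: float) -> np.ndarray:
        return np.linalg.solve(np.exp(lam * S), np.ones(len(S)))

    def excess(lam: float) -> float:
        try:
            return float(background(lam).sum() - 1.0)
        except np.linalg.LinAlgError:
            return np.nan

    # bracket the root on a geometric grid of candidate scales
    grid = np.geomspace(1e-3, 5.0, 400)
    vals = np.array([excess(l) for l in grid])
    lam_star = None
    for i in range(len(grid) - 1):
        a, b = vals[i], vals[i + 1]
        if np.isfinite(a) and np.isfinite(b) and np.sign(a) != np.sign(b):
            lam = brentq(excess, grid[i], grid[i + 1], xtol=1e-13, rtol=1e-14)
            p = background(lam)
            if (p > 0).all():
                lam_star = lam
                break
    if lam_star is None:
        raise DerivationError(
            "no positive scale makes the implied frequencies a proper joint "
            "distribution; is this a valid log-odds matrix?"
        )
    p = background(lam_star)
    q = np.outer(p, p) * np.exp(lam_star * S)
    total = q.sum()
    if abs(total - 1.0) > 1e-10:
        raise DerivationError(f"implied joint distribution sums to {total}, not 1")
    if np.abs(q - q.T).max() > 1e-6:
        raise DerivationError("implied joint distribution is not symmetric")
    cond = q / p[:, None]
    cond /= cond.sum(axis=1, keepdims=True)  # absorb root-finder residual
    return ConditionalSubstitutionModel(letters, p / p.sum(), cond)


def tune_self_emission(
    model: ConditionalSubstitutionModel, target_mean: float
) -> ConditionalSubstitutionModel:
    """Raise the mean self-emission to *target_mean* by one global factor.

    All off-diagonal entries are scaled by γ = (1 − target) / (1 − current
    mean); diagonals absorb the difference, so relative mutation preferences
    within each row are preserved exactly.  Tuning only ever reduces
    mutation: a target below the current mean raises ``ValueError``.
    """
    if not 0.0 < target_mean <= 1.0:
        raise ValueError("target mean self-emission must be in (0, 1]")
    current = model.mean_self_emission
    if target_mean < current - 1e-12:
        raise ValueError(
            f"target mean {target_mean:.4f} is below the current mean "
            f"{current:.4f}; tuning only reduces mutation"
        )
    gamma = (1.0 - target_mean) / (1.0 - current)
    cond = model.conditional * gamma
    np.fill_diagonal(cond, 1.0 - gamma * (1.0 - np.diag(model.conditional)))
    return ConditionalSubstitutionModel(model.alphabet, model.background.copy(), cond)


def tune_self_emission_per_row(
    model: ConditionalSubstitutionModel, target: float
) -> ConditionalSubstitutionModel:
    """Alternative tuning mode: force every row's p(a|a) to *target* with a
    per-row off-diagonal scale.  Exposed for comparison; the global mode is
    canonical."""
    diag = np.diag(model.conditional)
    if (target < diag - 1e-12).any():
        raise ValueError("target below some row's current self-emission")
    gam = (1.0 - target) / (1.0 - diag)
    cond = model.conditional * gam[:, None]
    np.fill_diagonal(cond, target)
    return ConditionalSubstitutionModel(model.alphabet, model.background.copy(), cond)


def mutate(seq: SequenceRecord, model: ConditionalSubstitutionModel, seed: int) -> SequenceRecord:
    """Resample each position independently from p(·|s_i).

    Mask-symbol positions pass through unchanged; any other residue outside
    the model's alphabet is an error.
    """
    lut = np.full(128, -1, dtype=np.int64)
    for i, c in enumerate(model.alphabet):
        lut[ord(c)] = i
    codes = lut[np.frombuffer(seq.residues.encode(), dtype=np.uint8)]
    bad = (codes < 0) & ~seq.mask
    if bad.any():
        pos = int(np.nonzero(bad)[0][0])
        raise ValueError(
            f"residue {seq.residues[pos]!r} at position {pos} is outside the model alphabet"
        )
    rng = np.random.default_rng((seed, 23))
    u = rng.random(len(seq))
    cum = np.cumsum(model.conditional, axis=1)
    cum[:, -1] = 1.0
    out = np.array(list(seq.residues))
    unmasked = ~seq.mask
    rows = cum[codes[unmasked]]
    drawn = (u[unmasked][:, None] > rows).sum(axis=1)
    letters = np.array(list(model.alphabet))
    out[unmasked] = letters[drawn]
    return SequenceRecord(seq.tagged("mut"), seq.alphabet, "".join(out))
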