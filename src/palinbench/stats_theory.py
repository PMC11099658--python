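"""Distributional statistics and closed-form expected-length theory.

The match amplitude λ₂ is the probability that two independently drawn
letters agree: λ₂ = Σ_i p_i², which is 1/s for a uniform s-letter alphabet.
It governs the classical expectations

* longest common substring of two length-k strings:  2·log_{1/λ₂}(k)
* longest palindromic substring of one length-k string:  2·log_{1/λ₂}(k) + 1
* longest α-gapped palindrome (w = u v ū, α ≥ (|u|+|v|)/|u|):
  (α + 1)·log_{1/λ₂}(k), equivalently (β + 2)·log_{1/λ₂}(k) with β = α − 1.

Alignment-score tails are summarised with a Gumbel (maximum extreme-value)
fit; :func:`tail_ratio` compares two fitted tails at a score, the pattern
used to quantify how much more often reversed decoys reach a rare score than
honest shuffles do.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .records import ALPHABETS


@dataclass
class TheoryParams:
    """Alphabet size, letter probabilities, and derived λ₂ = Σ p_i²."""

    alphabet_size: int
    letter_probabilities: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.letter_probabilities is None:
            self.letter_probabilities = np.full(self.alphabet_size, 1.0 / self.alphabet_size)
        p = np.asarray(self.letter_probabilities, dtype=float)
        if len(p) != self.alphabet_size or (p < 0).any() or abs(p.sum() - 1) > 1e-9:
            raise ValueError("invalid letter probability vector")
        self.letter_probabilities = p

    @classmethod
    def uniform(cls, s: int) -> "TheoryParams":
        return cls(s)

    @classmethod
    def for_alphabet(cls, alphabet: str) -> "TheoryParams":
        return cls(len(ALPHABETS[alphabet]))

    @property
    def lambda2(self) -> float:
        return float(np.square(self.letter_probabilities).sum())


def expected_lcs_length(k: float, theta: TheoryParams) -> float:
    """Expected longest common substring of two length-k strings:
    2·log(k)/log(1/λ₂)."""
    if k <= 1:
        raise ValueError("k must exceed 1")
    return 2.0 * math.log(k) / math.log(1.0 / theta.lambda2)


def expected_palindrome_length(k: float, theta: TheoryParams) -> float:
    """Expected longest palindromic substring of a length-k string:
    expected LCS plus one."""
    return expected_lcs_length(k, theta) + 1.0


def expected_gapped_palindrome_length(k: float, alpha: float, theta: TheoryParams) -> float:
    """Expected longest α-gapped palindrome: (α+1)·log(k)/log(1/λ₂).

    α = 1 recovers the LCS expectation; the (β+2) form with β = α − 1 is the
    same quantity.
    """
    if alpha < 1:
        raise ValueError("alpha must be >= 1 (|u|+|v| >= |u|)")
    return (alpha + 1.0) * math.log(k) / math.log(1.0 / theta.lambda2)


@dataclass
class GumbelFit:
    """Maximum-likelihood Gumbel (maximum) location/scale."""

    location: float
    scale: float
    n_observations: int

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValueError("Gumbel scale must be positive")

    def tail_prob(self, score: float) -> float:
        """P(S >= score) under the fit."""
        return float(stats.gumbel_r.sf(score, loc=self.location, scale=self.scale))


def fit_gumbel(scores) -> GumbelFit:
    """MLE Gumbel fit of a score sample (scipy's gumbel_r.fit).

    Requires at least 30 observations; constant input is degenerate and
    raises.
    """
    x = np.asarray(scores, dtype=float)
    if len(x) < 30:
        raise ValueError(f"need >= 30 observations to fit a Gumbel tail, got {len(x)}")
    if np.ptp(x) == 0:
        raise ValueError("degenerate (constant) score sample")
    loc, scale = stats.gumbel_r.fit(x)
    return GumbelFit(float(loc), float(scale), len(x))


def tail_ratio(fit_a: GumbelFit, fit_b: GumbelFit, score: float) -> float:
    """P_b(S ≥ score) / P_a(S ≥ score): how much more often distribution b
    reaches *score* than distribution a does."""
    pa = fit_a.tail_prob(score)
    pb = fit_b.tail_prob(score)
    if pa == 0:
        return math.inf if pb > 0 else math.nan
    return pb / pa


def compare_paired(scores_x, scores_y, method: str = "signed-rank") -> tuple[float, float]:
    """Two-sided Wilcoxon comparison of paired score lists.

    Returns ``(p_value, frac_higher)`` where ``frac_higher`` is the fraction
    of pairs with ``y_i > x_i`` (strict).  ``method`` selects the paired
    signed-rank test (canonical: pairs share an origin sequence) or the
    unpaired rank-sum test.  Zero differences are discarded, the standard
    convention; an all-zero difference vector yields p = 1.
    """
    x = np.asarray(scores_x, dtype=float)
    y = np.asarray(scores_y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired score lists must have equal length")
    frac_higher = float((y > x).mean())
    if method == "signed-rank":
        if np.all(x == y):
            return 1.0, frac_higher
        stat = stats.wilcoxon(x, y, zero_method="wilcox", alternative="two-sided")
        return float(stat.pvalue), frac_higher
    if method == "rank-sum":
        stat = stats.mannwhitneyu(x, y, alternative="two-sided")
        return float(stat.pvalue), frac_higher
    raise ValueError(f"unknown method {method!r}")
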