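# Methods

## The phenomenon being measured

A local alignment between a sequence `s` and `reverse(s)` is, after a change
of coordinates, a self-alignment of `s` read forwards against itself read
backwards: a collinear path in the (query, reversed-target) matrix is an
anti-collinear path in (query, query). Exact such matches are palindromic
substrings; gapped and mismatched ones are approximate palindromes. The
package quantifies how much this structural fact inflates alignment scores
against reversed decoys, under controlled synthetic conditions, and provides
the corrective (filter targets by identity before reversing).

Closed-form anchors (uniform or near-uniform letter usage, match amplitude
λ₂ = Σ pᵢ²):

- E[LCS of two length-k strings] ≈ 2·log₁/λ₂(k)
- E[LPS of one length-k string] ≈ 2·log₁/λ₂(k) + 1
- E[longest α-gapped palindrome] ≈ (α+1)·log₁/λ₂(k); writing β = α − 1 this
  is the (β+2)-form. (α = 1 degenerates to the LCS expectation.)

At k = 400, s = 20 these give 4 and 5 exactly, which is what the Monte-Carlo
checks in the test suite assert (200 sequences per check).

A relation used for cross-validation: every palindromic substring of `s` is
a common substring of `s` and `reverse(s)`, hence
`LCS(s, reverse(s)) ≥ LPS(s)`. Equality is *typical* for random sequences
but not guaranteed — the LCS may instead be a reversed repeat (a word
occurring forwards at one position and backwards at another, e.g. `CA`/`AC`
in `CADEAC`). Tests assert the inequality and check that equality holds for
the majority of random sequences.

## Sequence model and generator

`SequenceRecord` carries one sequence over a 20-letter protein or 4-letter
DNA alphabet plus a hard-mask symbol (`X`/`N`); mask flags are identical to
mask-symbol positions by construction. Ambiguity codes are rejected: every
statistical model here is defined over the canonical letters.

The generator draws i.i.d. letters from a stated composition with lengths
from a fixed, uniform-range, or empirical sampler. Defaults are the study
conditions used throughout: **uniform composition** (so λ₂ = 1/20 exactly
and the theory curves are parameter-free) and **lengths uniform on
[280, 320]**, the window used for the score-distribution analyses. A
Swiss-Prot-wide composition table is provided for realism experiments. One
top-level seed governs everything; per-sequence substreams are derived as
`default_rng((seed, index))` so enlarging n never reshuffles earlier
sequences.

What the generator does *not* emulate: domain architecture, codon structure,
position-dependent composition, indel evolution, or the long-tailed length
distribution of real proteomes. Tandem repeats and low-complexity runs are
emulated explicitly by `insert_repeat` (unit, copy number, per-position
substitution rate) because they are the one biological feature the analysis
must control for. Consequently, passing tests demonstrate the *reversal*
effect and its corrections in clean sequences; magnitudes on real data
(which add repeat- and composition-driven inflation) will differ, in the
direction the masking experiments indicate.

## Conditional substitution model

A symmetric integer log-odds matrix `s_ab` (half-bits for the BLOSUM family)
implies target frequencies via the unique scale λ\* > 0 at which
`q_ab = p(a)p(b)·exp(λ* s_ab)` is a proper joint distribution with marginals
`p`. Marginal consistency reduces to the linear system `exp(λ*S)·p = 1`;
λ\* is found by bracketing + Brent root-finding on Σp − 1 (tolerance 1e-13
on λ, 1e-10 on Σq), and the conditional rows are `p(b|a) = q_ab / p(a)`.
Validation: the same inversion applied to BLOSUM62 recovers the known
ungapped scale (0.324 vs the textbook 0.3176) and the known background
frequencies to |Δ| ≤ 0.016 — the residuals are the integer rounding of the
published matrices.

For BLOSUM90 the inversion gives a mean self-emission (unweighted mean over
the 20 letters of p(a|a)) of **46.42 %**, with a background-weighted mean of
46.12 %. Values computed from unrounded frequency data would land a few
tenths of a point lower; the package reports what the published integer
matrix implies, and both weighted and unweighted summaries are exposed
(`weighted_self_emission`, `mean_self_emission`; the unweighted mean is the
canonical one, matching the convention of quoting a single per-matrix
number).

Tuning to a higher conservation level multiplies **all** off-diagonal
conditional entries by one global γ = (1 − target)/(1 − current mean), the
minimal transformation that preserves every relative mutation preference;
the diagonal absorbs the difference. A per-row variant (every p(a|a) forced
to the target) is exposed for comparison but is not the default. Tuning
below the current mean is refused — the model only ever becomes more
conserved. After tuning, the joint distribution is no longer exactly
symmetric off the original diagonal scale; this is documented rather than
corrected, since only the conditionals are sampled.

`mutate` resamples every unmasked position independently from p(·|sᵢ);
masked positions pass through. There are no indels, matching the
substitution-only divergence model the gradient experiments need.

## String algorithms

**Palindromes.** Manacher's algorithm on a separator-augmented array gives
the maximal palindrome at all 2L−1 centres in O(L). Masked residues are
encoded as per-position unique symbols so they match nothing, including
themselves; the maximal palindrome centred on a masked residue is defined as
length 0. Intervals are 0-based half-open everywhere.

**LCS.** A suffix automaton over the first sequence is streamed with the
second (linear time, dict transitions so the mask-unique encoding works);
exact-matching Smith–Waterman (all mismatch/gap scores at −10¹²) provides
the dual route used in tests.

**Smith–Waterman.** Gotoh three-state affine DP in numba kernels
(score-only O(m)-memory for surveys; full-matrix with traceback when
intervals and identity are needed). Gap convention: a length-g gap costs
open + (g−1)·extend with open = 11, extend = 1 (BLOSUM62 half-bit units),
i.e. the open penalty is charged on the first gapped position. Traceback
ties break diagonal > up > left, which can affect intervals but never
scores. The mask symbol scores through the matrix's own X row (as aligners
do on hard-masked input) — deliberately different from the palindrome
module's stricter never-match policy, and the reason LCS-vs-SW
cross-checks run on unmasked input. Oracles: a Waterman–Smith–Beyer
explicit-gap-length DP (different recurrence), a full path-enumeration
oracle at tiny sizes, and Biopython's `PairwiseAligner` in local mode.

**Identity** is matches / alignment columns, gap columns included in the
denominator — the conservative choice for decoy filtering (borderline
targets are more likely to be dropped).

## Masking

The built-in tandem masker is a transparent period scan: for each period
p ≤ 10 it finds runs of `seq[i] == seq[i−p]` allowing a mismatch fraction
≤ 0.2, keeps runs spanning at least (min_copies − 1)·p = 2p matched offsets,
and hard-masks the run plus its leading unit. The scan iterates to a
fixpoint, which makes masking exactly idempotent. It is deliberately *not* a
re-implementation of any probabilistic masker — it is simple enough to test
exhaustively, and an external-tool hook (`external_mask`, subprocess with
output-length validation) is available for users who want a production
masker. Measured false-positive rate on uniform random 300-mers: ≤ 2 % of
positions.

## Statistics

Score tails are summarised by maximum-likelihood Gumbel fits
(`scipy.stats.gumbel_r.fit`; ≥ 30 observations required, constant samples
rejected). `tail_ratio` compares two fitted exceedance probabilities at a
score — the pattern used to express "how much more often do reversed decoys
reach this score". Paired comparisons use the two-sided Wilcoxon signed-rank
test (pairs share an origin sequence by construction; zero differences
discarded by the standard convention), with the unpaired rank-sum variant
exposed as an option. The exceedance fraction reported alongside is the
strict fraction of pairs where the second list wins.

## Experiments and problem sizes

All experiments run from (config, seed) and write TSV + JSON manifests
(config, seed, package version) when given an output directory. Default
sizes — 500 pairs for score-shift, 300 pairs per gradient point, 200
sequences for the all-vs-all self-vs-cross scan, lengths 280–320 — complete
in seconds to tens of seconds on one CPU and give stable directions and
comfortable significance margins at the effect sizes involved; larger runs
are a config change.

- **Score shift**: four pairings (independent partner, shuffled partner,
  own reversal, reversal of the shuffle). The reversal pairings are
  right-shifted by ~15 half-bits at these lengths; ~90 % of pairs beat
  their independent-partner score.
- **Mutation gradient**: reversals mutated at mean identities from the
  untuned ~46 % up to 90 %, compared against the independent baseline.
  Medians rise monotonically with conservation. One caveat, measured and
  documented in the acceptance test: even at ~46 % identity a small residual
  reversal affinity survives in clean synthetic sequences, so its
  significance hovers at the α = 0.01 boundary for n = 300 — in real-data
  comparisons this residual is swallowed by the repeat-driven elevation of
  the biological baseline.
- **Self-vs-cross**: all n×n query-versus-reversal scores; the threshold is
  a high quantile (default 0.995) of the off-diagonal distribution, and the
  reported enrichment is (self-hit rate)/(cross-hit rate), i.e. normalised
  by the (n−1)× opportunity factor. Typical values at n = 200 are tens of
  times above 1.
- **Palindrome / digest curves**: per-length-bin means of LPS and LCS with
  the theory overlay; the digest variant runs on tryptic fragments
  (three-way splits of every cleavage-site pair, 5–100 aa retained,
  de-duplicated by interval — duplicates would only reweight bins). The
  trypsin rule is the standard one (cleave after K/R except before P); a
  `literal_rule` flag inverts the proline condition for auditability.

## Safe decoy generation

`make_safe_decoys` hard-masks the targets (optional but default), aligns
every target against every query, drops any target whose best-scoring
alignment reaches 50 % identity (exactly 50 % is dropped), and reverses the
survivors, emitting a per-target report. The identity is taken from the
best-*scoring* alignment: taking the maximum identity over all alignments
would let short spurious high-identity local hits disqualify genuinely
unrelated targets. An opt-in shared-4-mer prefilter skips hopeless pairs;
it is off by default so the filter is exact. Cost is O(|Q|·|T|) full DP.

## Known limitations

- Desk-scale synthetic runs reproduce directions and theory-anchored
  magnitudes, not the headline numbers of real-database studies (those
  depend on database content and scale).
- E-values are deliberately out of scope; scores are compared directly and
  tails are handled by Gumbel fits.
- The DNA path reuses the protein machinery over the 4-letter alphabet with
  a simple match/mismatch scheme; no strand-specific biology is modelled
  (reversal here is never reverse complementation).
- The naming of "LPS" follows longest palindromic *substring* semantics
  throughout; contexts that say "subsequence" for the same quantity are a
  known terminology hazard, and nothing here computes the (different)
  longest palindromic subsequence.
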