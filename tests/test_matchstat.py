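"""Smith-Waterman alignment and LCS machinery against independent oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from palinbench.matchstat import ScoringScheme, lcs, score_by_length, sw_align, sw_score
from palinbench.palindrome import lps_length
from palinbench.records import DNA, PROTEIN, SequenceRecord
from palinbench.synthetic import CompositionSpec, generate_random
from palinbench.transforms import reverse

from conftest import dna, protein


def wsb_score(a, b, sub, gap_open, gap_extend):
    """Waterman-Smith-Beyer general-gap-cost local DP (explicit gap lengths).

    Independent oracle: a different recurrence from the Gotoh three-state
    kernel; cubic time, fine for tiny strings.
    """
    n, m = len(a), len(b)
    H = np.zeros((n + 1, m + 1), dtype=np.int64)
    best = 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            cand = max(0, H[i - 1, j - 1] + sub[a[i - 1], b[j - 1]])
            for g in range(1, i + 1):  # gap consuming a[i-g:i]
                cand = max(cand, H[i - g, j] - gap_open - (g - 1) * gap_extend)
            for g in range(1, j + 1):
                cand = max(cand, H[i, j - g] - gap_open - (g - 1) * gap_extend)
            H[i, j] = cand
            best = max(best, cand)
    return best


def enumerate_alignments_best(a, b, sub, gap_open, gap_extend):
    """Exhaustive enumeration over all gapped local alignment paths."""
    best = 0

    def walk(i, j, score, state):
        nonlocal best
        best = max(best, score)
        if i < len(a) and j < len(b):
            walk(i + 1, j + 1, score + sub[a[i], b[j]], "M")
        if i < len(a):
            cost = gap_extend if state == "A" else gap_open
            walk(i + 1, j, score - cost, "A")
        if j < len(b):
            cost = gap_extend if state == "B" else gap_open
            walk(i, j + 1, score - cost, "B")

    for i0 in range(len(a)):
        for j0 in range(len(b)):
            walk(i0, j0, 0, "M")
    return best


def brute_lcs(x: str, y: str) -> int:
    subs = {x[i:j] for i in range(len(x)) for j in range(i + 1, len(x) + 1)}
    return max((j - i for i in range(len(y)) for j in range(i + 1, len(y) + 1)
                if y[i:j] in subs), default=0)


@pytest.fixture(scope="module")
def dna_scheme():
    return ScoringScheme.dna(match=2, mismatch=-3, gap_open=5, gap_extend=2)


class TestSmithWaterman:
    def test_blosum62_diagonal_example(self, blosum62_scheme):
        r = sw_align(protein("WWW"), protein("WWW", id="t"), blosum62_scheme)
        assert r.score == 33  # 3 x W:W = 11 in half-bit BLOSUM62
        assert r.identity_fraction == 1.0
        assert r.query_interval == (0, 3) and r.target_interval == (0, 3)

    def test_all_negative_pair_scores_zero(self, blosum62_scheme):
        r = sw_align(protein("WWWW"), protein("PPPP", id="t"), blosum62_scheme)
        assert r.score == 0
        assert r.query_interval == (0, 0) and r.target_interval == (0, 0)

    def test_matches_wsb_oracle_on_random_short_pairs(self, dna_scheme):
        rng = np.random.default_rng(10)
        sub, go, ge = dna_scheme.matrix, dna_scheme.gap_open, dna_scheme.gap_extend
        for _ in range(300):
            la, lb = rng.integers(1, 8, size=2)
            a = rng.integers(0, 4, size=la)
            b = rng.integers(0, 4, size=lb)
            ra = SequenceRecord("a", DNA, "".join("ACGT"[k] for k in a))
            rb = SequenceRecord("b", DNA, "".join("ACGT"[k] for k in b))
            assert sw_score(ra, rb, dna_scheme) == wsb_score(a, b, sub, go, ge)

    def test_matches_full_path_enumeration_tiny(self, dna_scheme):
        rng = np.random.default_rng(11)
        sub, go, ge = dna_scheme.matrix, dna_scheme.gap_open, dna_scheme.gap_extend
        for _ in range(25):
            la, lb = rng.integers(1, 5, size=2)
            a = rng.integers(0, 4, size=la)
            b = rng.integers(0, 4, size=lb)
            ra = SequenceRecord("a", DNA, "".join("ACGT"[k] for k in a))
            rb = SequenceRecord("b", DNA, "".join("ACGT"[k] for k in b))
            assert sw_score(ra, rb, dna_scheme) == \
                enumerate_alignments_best(a, b, sub, go, ge)

    def test_matches_biopython_pairwise_aligner(self, blosum62_scheme):
        """Cross-check the affine kernel against an established independent
        implementation on protein pairs (same gap convention)."""
        from Bio import Align
        from Bio.Align import substitution_matrices

        aligner = Align.PairwiseAligner()
        aligner.mode = "local"
        aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
        aligner.open_gap_score = -11
        aligner.extend_gap_score = -1
        spec = CompositionSpec.uniform_protein(("uniform_range", 20, 60))
        seqs = generate_random(spec, 40, seed=14)
        for q, t in zip(seqs[:20], seqs[20:]):
            assert sw_score(q, t, blosum62_scheme) == int(aligner.score(q.residues, t.residues))

    def test_symmetry_for_symmetric_matrix(self, blosum62_scheme):
        spec = CompositionSpec.uniform_protein(("fixed", 40))
        a, b = generate_random(spec, 2, seed=15)
        assert sw_score(a, b, blosum62_scheme) == sw_score(b, a, blosum62_scheme)

    def test_monotone_under_appending(self, blosum62_scheme):
        spec = CompositionSpec.uniform_protein(("fixed", 30))
        a, b = generate_random(spec, 2, seed=16)
        base = sw_score(a, b, blosum62_scheme)
        longer = SequenceRecord("a2", PROTEIN, a.residues + "WKY")
        assert sw_score(longer, b, blosum62_scheme) >= base

    def test_gap_cost_convention(self, dna_scheme):
        # single internal gap of length 2: 10 matches (20) minus open 5 plus
        # one extension 2 = 13 (a length-g gap costs open + (g-1)*extend)
        q = dna("ACGGTCTTCAAG")
        t = dna("ACGGTCCAAG", id="t")
        assert sw_score(q, t, dna_scheme) == 13

    def test_alphabet_mismatch_rejected(self, blosum62_scheme):
        with pytest.raises(ValueError, match="alphabet"):
            sw_score(dna("ACGT"), dna("ACGT"), blosum62_scheme)

    def test_mask_symbol_uses_matrix_wildcard_row(self, blosum62_scheme):
        # X scores via BLOSUM62's own X row (A:X = 0 there), not forced
        # non-matching: the best path runs straight through the masked residue
        sym = blosum62_scheme.symbols
        M = blosum62_scheme.matrix
        aa = M[sym.index("A"), sym.index("A")]
        ax = M[sym.index("A"), sym.index("X")]
        r = sw_align(protein("AXA"), protein("AAA", id="t"), blosum62_scheme)
        assert r.score == 2 * aa + ax

    def test_identity_counts_gap_columns_in_denominator(self, dna_scheme):
        q = dna("ACGGTCTTCAAG")
        t = dna("ACGGTCCAAG", id="t")
        r = sw_align(q, t, dna_scheme)
        assert r.n_gap_columns == 2
        assert r.identity_fraction == pytest.approx(10 / 12)


class TestLCS:
    def test_lcs_of_self_is_length(self):
        s = protein("ACDEFGHIKL")
        length, ai, bi = lcs(s, s)
        assert length == len(s) and ai == (0, 10) and bi == (0, 10)

    def test_known_overlap(self):
        # classic overlap: "ANANA" shared by CANANA / ANANAS
        length, ai, bi = lcs(protein("CANANA"), protein("ANANAS", id="b"))
        assert length == 5
        assert protein("CANANA").residues[ai[0]:ai[1]] == "ANANA"
        assert protein("ANANAS").residues[bi[0]:bi[1]] == "ANANA"

    def test_against_brute_force_on_random_pairs(self):
        rng = np.random.default_rng(17)
        letters = np.array(list("ACGT"))
        for _ in range(1000):
            x = "".join(rng.choice(letters, size=int(rng.integers(1, 40))))
            y = "".join(rng.choice(letters, size=int(rng.integers(1, 40))))
            got, ai, bi = lcs(SequenceRecord("x", DNA, x), SequenceRecord("y", DNA, y))
            assert got == brute_lcs(x, y), (x, y)
            assert x[ai[0]:ai[1]] == y[bi[0]:bi[1]]

    def test_exact_only_sw_equals_suffix_automaton(self):
        """Dual route: SW with effectively infinite mismatch/gap penalties
        reports exactly the LCS length."""
        exact = ScoringScheme.exact(PROTEIN)
        spec = CompositionSpec.uniform_protein(("uniform_range", 30, 80))
        seqs = generate_random(spec, 200, seed=18)
        for q, t in zip(seqs[:100], seqs[100:]):
            assert sw_score(q, t, exact) == lcs(q, t)[0]

    def test_lcs_vs_reversal_bounds_lps_bulk(self):
        """LCS(s, rev s) >= LPS(s) always; for random protein sequences the
        two coincide most of the time (reversed repeats are as rare as
        palindromes)."""
        spec = CompositionSpec.uniform_protein(("uniform_range", 50, 200))
        seqs = generate_random(spec, 100, seed=19)
        equal = 0
        for s in seqs:
            l_lcs = lcs(s, reverse(s))[0]
            l_lps = lps_length(s)
            assert l_lcs >= l_lps
            equal += l_lcs == l_lps
        assert equal > 50


class TestScoreByLength:
    def test_equal_length_bin_key(self, blosum62_scheme):
        spec = CompositionSpec.uniform_protein(("fixed", 300))
        a, b = generate_random(spec, 2, seed=20)
        df = score_by_length([(a, b)], blosum62_scheme, bins=[0, 299, 301, 1000])
        assert df["count"].tolist() == [0, 1, 0]

    def test_geometric_mean_bin_key(self, blosum62_scheme):
        sa = generate_random(CompositionSpec.uniform_protein(("fixed", 100)), 1, 1)[0]
        sb = generate_random(CompositionSpec.uniform_protein(("fixed", 400)), 1, 2)[0]
        # sqrt(100*400) = 200
        df = score_by_length([(sa, sb)], blosum62_scheme, bins=[0, 199, 201, 1000])
        assert df["count"].tolist() == [0, 1, 0]

    def test_constant_scores_mean(self, blosum62_scheme):
        a = protein("WWWW")
        b = protein("WWWW", id="b")
        df = score_by_length([(a, b), (a, b)], blosum62_scheme, bins=[0, 10])
        assert df.mean_score[0] == 44.0 and df["count"][0].item() == 2
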