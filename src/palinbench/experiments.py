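"""Desk-scale replicas of the core analyses, built entirely from synthetic
sequences.

Each experiment is reproducible from (config, seed) and, when given an output
directory, writes its tables as TSV plus a JSON manifest (config, seed,
package version).  Default problem sizes are chosen to run on one CPU in
minutes: 500 pairs for score-shift distributions, 300 pairs per point on the
mutation gradient, all-vs-all capped at 200 sequences; lengths default to the
280–320 window used for the tail analyses.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .masking import mask_tandem
from .matchstat import ScoringScheme, lcs, sw_score
from .mutmodel import derive_from_logodds, mutate, tune_self_emission
from .palindrome import lps_length
from .records import SequenceRecord
from .stats_theory import TheoryParams, compare_paired, expected_lcs_length, \
    expected_palindrome_length
from .synthetic import CompositionSpec, generate_random
from .transforms import reverse, shuffle

log = logging.getLogger("palinbench")


def _manifest(out_dir, name: str, config: dict) -> None:
    if out_dir is None:
        return
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / f"{name}.manifest.json", "w") as fh:
        json.dump({"experiment": name, "package_version": __version__, **config}, fh, indent=1)


def _independent_partners(seqs: list[SequenceRecord], spec: CompositionSpec,
                          seed: int) -> list[SequenceRecord]:
    """Fresh random sequences matched in length index-by-index."""
    out = []
    for i, s in enumerate(seqs):
        one = CompositionSpec(spec.alphabet, spec.letter_probabilities,
                              ("fixed", len(s)))
        rec = generate_random(one, 1, (seed ^ 0x5A5A) + 1000 + i)[0]
        out.append(SequenceRecord(f"indep{i:05d}", rec.alphabet, rec.residues))
    return out


def exp_score_shift(n: int = 500, length_range: tuple[int, int] = (280, 320),
                    seed: int = 0, spec: CompositionSpec | None = None,
                    scheme: ScoringScheme | None = None,
                    out_dir=None) -> tuple[pd.DataFrame, dict]:
    """Score distributions for the four core pairings.

    Pairings: seq↔shuffle(seq), seq↔reverse(seq), shuffle↔reverse(shuffle)
    and seq↔independent random.  Returns the per-pair score table and, for
    each pairing, a paired Wilcoxon comparison against the independent
    baseline (p-value, exceedance fraction, median).
    """
    t0 = time.time()
    spec = spec or CompositionSpec.uniform_protein(("uniform_range", *length_range))
    scheme = scheme or ScoringScheme.blosum62()
    seqs = generate_random(spec, n, seed)
    indep = _independent_partners(seqs, spec, seed)
    pairings = {}
    pairings["seq_vs_indep"] = [(s, t) for s, t in zip(seqs, indep)]
    pairings["seq_vs_shuf"] = [(s, shuffle(s, seed + i)) for i, s in enumerate(seqs)]
    pairings["seq_vs_rev"] = [(s, reverse(s)) for s in seqs]
    shufs = [shuffle(s, seed + i) for i, s in enumerate(seqs)]
    pairings["shuf_vs_shufrev"] = [(sh, reverse(sh)) for sh in shufs]
    rows = []
    for name, pairs in pairings.items():
        for i, (q, t) in enumerate(pairs):
            rows.append({"pairing": name, "pair_index": i, "length": len(q),
                         "score": sw_score(q, t, scheme)})
        log.info("scored %s (%d pairs, %.1fs)", name, len(pairs), time.time() - t0)
    df = pd.DataFrame(rows)
    base = df[df.pairing == "seq_vs_indep"].score.to_numpy()
    stats = {}
    for name in pairings:
        sc = df[df.pairing == name].score.to_numpy()
        p, frac = compare_paired(base, sc)
        stats[name] = {"median": float(np.median(sc)), "wilcoxon_p_vs_indep": p,
                       "frac_higher_than_indep": frac}
    _manifest(out_dir, "score_shift", {"n": n, "length_range": list(length_range),
                                       "seed": seed})
    if out_dir is not None:
        df.to_csv(Path(out_dir) / "score_shift.tsv", sep="\t", index=False)
        with open(Path(out_dir) / "score_shift.stats.json", "w") as fh:
            json.dump(stats, fh, indent=1)
    return df, stats


def exp_mutation_gradient(n: int = 300, targets=(None, 0.50, 0.60, 0.70, 0.80, 0.90),
                          length_range: tuple[int, int] = (280, 320), seed: int = 0,
                          matrix: str = "BLOSUM90",
                          out_dir=None) -> tuple[pd.DataFrame, dict]:
    """Reversal affinity as a function of decoy divergence.

    For each self-emission target the reversal of each shuffled sequence is
    mutated under the tuned conditional model, then SW-scored against the
    unreversed sequence.  ``None`` in *targets* means the untuned
    matrix-derived model (the most diverged variant; tuning can only make a
    model more conserved).  Scores are compared to the seq↔independent
    baseline.
    """
    spec = CompositionSpec.uniform_protein(("uniform_range", *length_range))
    scheme = ScoringScheme.blosum62()
    base_model = derive_from_logodds(matrix)
    seqs = generate_random(spec, n, seed)
    indep = _independent_partners(seqs, spec, seed)
    baseline = np.array([sw_score(s, t, scheme) for s, t in zip(seqs, indep)])
    rows = [{"target": "baseline", "self_emission": np.nan, "pair_index": i,
             "score": int(v)} for i, v in enumerate(baseline)]
    stats = {}
    for target in targets:
        model = base_model if target is None else tune_self_emission(base_model, target)
        label = f"{100 * model.mean_self_emission:.0f}pct"
        scores = []
        for i, s in enumerate(seqs):
            decoy = mutate(reverse(s), model, seed + 31 * i)
            scores.append(sw_score(s, decoy, scheme))
        scores = np.array(scores)
        p, frac = compare_paired(baseline, scores)
        stats[label] = {"self_emission": model.mean_self_emission,
                        "median": float(np.median(scores)),
                        "wilcoxon_p_vs_baseline": p, "frac_higher": frac}
        rows += [{"target": label, "self_emission": model.mean_self_emission,
                  "pair_index": i, "score": int(v)} for i, v in enumerate(scores)]
        log.info("mutation gradient %s done", label)
    df = pd.DataFrame(rows)
    _manifest(out_dir, "mutation_gradient", {"n": n, "seed": seed,
                                             "targets": [t for t in targets if t],
                                             "matrix": matrix})
    if out_dir is not None:
        df.to_csv(Path(out_dir) / "mutation_gradient.tsv", sep="\t", index=False)
        with open(Path(out_dir) / "mutation_gradient.stats.json", "w") as fh:
            json.dump(stats, fh, indent=1)
    return df, stats


def exp_self_vs_cross(n: int = 200, length_range: tuple[int, int] = (280, 320),
                      seed: int = 0, threshold_quantile: float = 0.995,
                      apply_mask: bool = True, out_dir=None) -> dict:
    """All-vs-all reversal search: are self-reversals over-represented among
    high scores?

    Scores all n×n pairs (query i vs reversal of query j), sets the score
    threshold at a high quantile of the cross (i≠j) distribution, and reports
    the self-enrichment ratio normalised by the (n−1)× opportunity factor:
    (n_self/n) / (n_cross/(n·(n−1))).
    """
    spec = CompositionSpec.uniform_protein(("uniform_range", *length_range))
    scheme = ScoringScheme.blosum62()
    seqs = generate_random(spec, n, seed)
    if apply_mask:
        seqs = [mask_tandem(s) for s in seqs]
    revs = [reverse(s) for s in seqs]
    enc = [scheme.encode(s) for s in seqs]
    encr = [scheme.encode(r) for r in revs]
    from ._sw import sw_score as _kernel
    scores = np.zeros((n, n), dtype=np.int64)
    t0 = time.time()
    for i in range(n):
        for j in range(n):
            scores[i, j] = _kernel(enc[i], encr[j], scheme.matrix,
                                   scheme.gap_open, scheme.gap_extend)
        if (i + 1) % 50 == 0:
            log.info("all-vs-all row %d/%d (%.1fs)", i + 1, n, time.time() - t0)
    off = ~np.eye(n, dtype=bool)
    cross = scores[off]
    threshold = float(np.quantile(cross, threshold_quantile))
    n_self = int((np.diag(scores) > threshold).sum())
    n_cross = int((cross > threshold).sum())
    self_rate = n_self / n
    cross_rate = n_cross / (n * (n - 1))
    enrichment = (self_rate / cross_rate) if cross_rate > 0 else (
        np.inf if n_self else np.nan)
    result = {"n": n, "threshold": threshold, "threshold_quantile": threshold_quantile,
              "n_self_hits": n_self, "n_cross_hits": n_cross,
              "normalized_self_enrichment": float(enrichment)}
    _manifest(out_dir, "self_vs_cross", {"n": n, "seed": seed,
                                         "threshold_quantile": threshold_quantile})
    if out_dir is not None:
        with open(Path(out_dir) / "self_vs_cross.json", "w") as fh:
            json.dump(result, fh, indent=1)
    return result


def exp_palindrome_curves(seqs: list[SequenceRecord], seed: int = 0,
                          bins=None, apply_mask: bool = False,
                          theta: TheoryParams | None = None,
                          out_dir=None) -> pd.DataFrame:
    """Per-length-bin mean LPS and LCS with the closed-form theory overlay.

    LCS is computed between each sequence and its shuffled partner.  With
    *apply_mask* the sequences are hard-masked first (the masking-collapse
    comparison).  Works for protein and DNA alike.
    """
    if not seqs:
        raise ValueError("need sequences")
    theta = theta or TheoryParams.for_alphabet(seqs[0].alphabet)
    if apply_mask:
        seqs = [mask_tandem(s) for s in seqs]
    lengths = np.array([len(s) for s in seqs], dtype=float)
    if bins is None:
        bins = np.linspace(lengths.min(), lengths.max() + 1, 11)
    edges = np.asarray(bins, dtype=float)
    lps = np.array([lps_length(s) for s in seqs], dtype=float)
    lcs_len = np.array([lcs(s, shuffle(s, seed + i))[0]
                        for i, s in enumerate(seqs)], dtype=float)
    which = np.digitize(lengths, edges) - 1
    rows = []
    for b in range(len(edges) - 1):
        sel = which == b
        mid = 0.5 * (edges[b] + edges[b + 1])
        rows.append({
            "bin_lo": edges[b], "bin_hi": edges[b + 1], "bin_mid": mid,
            "count": int(sel.sum()),
            "mean_lps": float(lps[sel].mean()) if sel.any() else np.nan,
            "mean_lcs": float(lcs_len[sel].mean()) if sel.any() else np.nan,
            "expected_lps": expected_palindrome_length(mid, theta),
            "expected_lcs": expected_lcs_length(mid, theta),
        })
    df = pd.DataFrame(rows)
    _manifest(out_dir, "palindrome_curves",
              {"n": len(seqs), "seed": seed, "apply_mask": apply_mask,
               "lambda2": theta.lambda2})
    if out_dir is not None:
        df.to_csv(Path(out_dir) / "palindrome_curves.tsv", sep="\t", index=False)
    return df


def exp_digest_curves(proteins: list[SequenceRecord], seed: int = 0,
                      min_len: int = 5, max_len: int = 100, bins=None,
                      out_dir=None) -> pd.DataFrame:
    """Tryptic-fragment LPS/LCS survey.

    Digests each protein (three-way splits, length filter), shuffles each
    fragment, and reports per-fragment-length-bin means of LPS(fragment),
    LPS(shuffled fragment) and LCS(fragment, shuffled fragment).
    """
    from .digest import fragment_record, three_way_fragments

    frags = []
    for prot in proteins:
        frags.extend(sorted(three_way_fragments(prot, min_len, max_len),
                            key=lambda f: (f.parent_id, f.start, f.end)))
    if not frags:
        raise ValueError("digestion produced no fragments in the length window")
    recs = [fragment_record(f) for f in frags]
    shufs = [shuffle(r, seed + i) for i, r in enumerate(recs)]
    lengths = np.array([len(r) for r in recs], dtype=float)
    lps_orig = np.array([lps_length(r) for r in recs], dtype=float)
    lps_shuf = np.array([lps_length(s) for s in shufs], dtype=float)
    lcs_len = np.array([lcs(r, s)[0] for r, s in zip(recs, shufs)], dtype=float)
    if bins is None:
        bins = np.arange(min_len, max_len + 6, 5, dtype=float)
    edges = np.asarray(bins, dtype=float)
    which = np.digitize(lengths, edges) - 1
    rows = []
    for b in range(len(edges) - 1):
        sel = which == b
        rows.append({
            "bin_lo": edges[b], "bin_hi": edges[b + 1], "count": int(sel.sum()),
            "mean_lps": float(lps_orig[sel].mean()) if sel.any() else np.nan,
            "mean_lps_shuffled": float(lps_shuf[sel].mean()) if sel.any() else np.nan,
            "mean_lcs": float(lcs_len[sel].mean()) if sel.any() else np.nan,
        })
    df = pd.DataFrame(rows)
    _manifest(out_dir, "digest_curves", {"n_proteins": len(proteins),
                                         "n_fragments": len(frags), "seed": seed,
                                         "min_len": min_len, "max_len": max_len})
    if out_dir is not None:
        df.to_csv(Path(out_dir) / "digest_curves.tsv", sep="\t", index=False)
    return df
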