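"""Safe reversed-decoy generation.

Reversed biological sequences make attractive decoys (they keep composition
and repetitiveness while destroying function), but a sequence aligns to its
own — or a homolog's — reversal far more often than chance because of
approximate palindromes.  The corrective: restrict the target set to
sequences with best-alignment identity below a threshold against every
query, and only reverse the survivors.

Percent identity here is matches / alignment columns (gap columns included
in the denominator) of the best local alignment — a conservative definition
that drops more borderline targets, erring toward decoy safety.  Identity
exactly at the threshold is dropped ("less than 50 %" survives).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .masking import mask_tandem
from .matchstat import ScoringScheme, sw_align
from .records import SequenceRecord
from .transforms import reverse

log = logging.getLogger("palinbench")


@dataclass
class DecoyReport:
    decoys: list[SequenceRecord]
    report: pd.DataFrame  # target_id, best_query_id, identity, score, kept


def _shares_kmer(a: str, b: str, k: int = 4) -> bool:
    kmers = {a[i:i + k] for i in range(len(a) - k + 1)}
    return any(b[i:i + k] in kmers for i in range(len(b) - k + 1))


def make_safe_decoys(
    queries: list[SequenceRecord],
    targets: list[SequenceRecord],
    identity_threshold: float = 0.50,
    mask_first: bool = True,
    scheme: ScoringScheme | None = None,
    kmer_prefilter: bool = False,
) -> DecoyReport:
    """Build reversal decoys free of reversal-induced self/homolog matches.

    Every target is aligned against every query; targets whose best
    alignment reaches ``identity_threshold`` are dropped, the rest are
    reversed and emitted.  With *mask_first* the targets are hard-masked
    before alignment (and the masked survivors are what gets reversed), so
    repeats cannot hide homology from the filter.  *kmer_prefilter* skips
    full DP for pairs sharing no 4-mer — an opt-in speedup, off by default.
    """
    if not queries or not targets:
        raise ValueError("query and target sets must both be nonempty")
    if any(q.alphabet != targets[0].alphabet for q in queries):
        raise ValueError("queries and targets must share an alphabet")
    scheme = scheme or ScoringScheme.blosum62()
    work = [mask_tandem(t) for t in targets] if mask_first else list(targets)
    rows = []
    decoys = []
    for t in work:
        # identity of the best-scoring alignment over all queries (ties keep
        # the higher identity, the conservative direction)
        best_identity, best_q, best_score = 0.0, None, -1
        for q in queries:
            if kmer_prefilter and not _shares_kmer(q.residues, t.residues):
                continue
            aln = sw_align(q, t, scheme)
            if aln.score > best_score or (
                aln.score == best_score and aln.identity_fraction > best_identity
            ):
                best_identity, best_q, best_score = aln.identity_fraction, q.id, aln.score
        best_score = max(best_score, 0)
        kept = best_identity < identity_threshold
        rows.append({"target_id": t.id, "best_query_id": best_q,
                     "identity": best_identity, "score": best_score, "kept": kept})
        if kept:
            decoys.append(reverse(t))
    if not decoys:
        log.warning("no targets survived the identity filter; decoy set is empty")
    return DecoyReport(decoys, pd.DataFrame(rows))
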