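"""Simulated trypsin digestion.

Trypsin cleaves C-terminal to lysine (K) or arginine (R) except when the next
residue is proline (P).  To emulate incomplete digestion the generator
enumerates every ordered pair of cleavage sites and emits the resulting
three-way split, then filters fragments to the 5–100 residue window that mass
spectrometers typically observe.  A ``literal_rule`` flag inverts the proline
exclusion (cleave only *before* proline) for auditability; the standard rule
is the default.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

from .records import PROTEIN, SequenceRecord

MIN_LEN, MAX_LEN = 5, 100


@dataclass(frozen=True)
class DigestFragment:
    parent_id: str
    start: int
    end: int
    residues: str

    def __len__(self) -> int:
        return self.end - self.start


def cleavage_sites(seq: SequenceRecord, literal_rule: bool = False) -> list[int]:
    """Positions immediately after each K/R, excluding cut points followed by
    proline (the standard trypsin rule); sorted ascending.  A C-terminal K/R
    yields the site L (its third fragment is empty and is removed by the
    length filter downstream)."""
    if seq.alphabet != PROTEIN:
        raise ValueError("trypsin digestion applies to protein sequences")
    s = seq.residues
    L = len(s)
    sites = []
    for i, c in enumerate(s):
        if c not in "KR":
            continue
        followed_by_p = i + 1 < L and s[i + 1] == "P"
        keep = followed_by_p if literal_rule else not followed_by_p
        if keep:
            sites.append(i + 1)
    return sites


def three_way_fragments(
    seq: SequenceRecord,
    min_len: int = MIN_LEN,
    max_len: int = MAX_LEN,
    literal_rule: bool = False,
) -> set[DigestFragment]:
    """All fragments from every three-way split (s_i, s_j) of the cleavage
    sites, filtered to [min_len, max_len] and de-duplicated by interval."""
    sites = cleavage_sites(seq, literal_rule=literal_rule)
    L = len(seq)
    out: set[DigestFragment] = set()
    for si, sj in combinations(sites, 2):
        for start, end in ((0, si), (si, sj), (sj, L)):
            if min_len <= end - start <= max_len:
                out.add(DigestFragment(seq.id, start, end, seq.residues[start:end]))
    return out


def fragment_record(frag: DigestFragment, alphabet: str = PROTEIN) -> SequenceRecord:
    """Materialise a fragment as a SequenceRecord (id ``parent|start-end``)."""
    return SequenceRecord(f"{frag.parent_id}|{frag.start}-{frag.end}", alphabet, frag.residues)
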