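"""Tandem-repeat hard-masking.

The built-in masker is a transparent period-scan: for each candidate period
p ≤ max_period it finds runs of positions where ``seq[i] == seq[i-p]`` with
bounded mismatch density; a run covering at least (min_copies − 1)·p matched
offsets marks the whole array (including the leading unit) for masking.
Masked positions are replaced by the hard-mask symbol (X for protein, N for
DNA) and never participate in further matching, which makes the operation
idempotent.  The scan is deliberately simple and testable rather than a
re-implementation of tantan's probabilistic model; an external-tool hook is
provided for users who want tantan itself.
"""

from __future__ import annotations

import shlex
import shutil
import subprocess
import tempfile
from pathlib import Path

import numpy as np

from .records import MASK_SYMBOL, SequenceRecord, read_fasta


def _runs_for_period(res: str, mask: np.ndarray, p: int, min_copies: int,
                     max_mismatch_frac: float) -> list[tuple[int, int]]:
    """Maximal qualifying runs at period p, as half-open residue intervals
    already widened to include the leading unit."""
    L = len(res)
    runs = []
    start = -1       # first offset index of the current run
    last_match = -1  # last matched offset in the current run
    mism = 0
    need = (min_copies - 1) * p

    def close() -> None:
        if start != -1 and last_match >= start and (last_match - start + 1) >= need:
            runs.append((start - p, last_match + 1))

    for i in range(p, L):
        ok = (not mask[i]) and (not mask[i - p]) and res[i] == res[i - p]
        if ok:
            if start == -1:
                start = i
                mism = 0
            last_match = i
        else:
            if start == -1:
                continue
            length = i - start + 1
            if mask[i] or mask[i - p] or (mism + 1) / length > max_mismatch_frac:
                close()
                start, last_match, mism = -1, -1, 0
            else:
                mism += 1
    close()
    return runs


def mask_tandem(
    seq: SequenceRecord,
    max_period: int = 10,
    min_copies: int = 3,
    max_mismatch_frac: float = 0.2,
) -> SequenceRecord:
    """Hard-mask detected tandem arrays; length unchanged; idempotent.

    The period scan is iterated to a fixpoint (masking can shorten a run at
    one period by interrupting it with another period's mask; rescanning
    until nothing changes makes the operation exactly idempotent).
    """
    msym = MASK_SYMBOL[seq.alphabet]
    residues, mask = seq.residues, seq.mask
    while True:
        to_mask = np.zeros(len(residues), dtype=bool)
        for p in range(1, max_period + 1):
            for lo, hi in _runs_for_period(residues, mask, p, min_copies, max_mismatch_frac):
                to_mask[lo:hi] = True
        new = to_mask & ~mask
        if not new.any():
            break
        chars = np.array(list(residues))
        chars[new] = msym
        residues = "".join(chars)
        mask = mask | new
    return SequenceRecord(seq.id, seq.alphabet, residues)


def external_mask(fasta_in, command_template: str, fasta_out, alphabet: str) -> Path:
    """Run an external masking tool on a FASTA file.

    *command_template* contains ``{}`` (or ``%s``) for the input path; the
    tool's stdout is taken as masked FASTA (lowercase or mask-symbol output
    both accepted).  Output sequence lengths are validated against the input
    — a mismatch is an error, never a silent passthrough.
    """
    tpl = command_template.replace("%s", "{}")
    if "{}" not in tpl:
        tpl = tpl + " {}"
    argv = shlex.split(tpl.format(shlex.quote(str(fasta_in))))
    exe = shutil.which(argv[0])
    if exe is None:
        raise FileNotFoundError(f"external masking tool {argv[0]!r} not found on PATH")
    proc = subprocess.run(argv, capture_output=True, text=True)
    if proc.returncode != 0:
        raise RuntimeError(f"{argv[0]} failed (exit {proc.returncode}): {proc.stderr[:500]}")
    with tempfile.NamedTemporaryFile("w", suffix=".fasta", delete=False) as tmp:
        tmp.write(proc.stdout)
        tmp_path = tmp.name
    original = read_fasta(fasta_in, alphabet)
    masked = read_fasta(tmp_path, alphabet, softmask_to_hard=True)
    if len(masked) != len(original) or any(
        len(m) != len(o) for m, o in zip(masked, original)
    ):
        raise RuntimeError(
            f"{argv[0]} output does not match input record count/lengths; refusing to import"
        )
    from .records import write_fasta

    write_fasta(masked, fasta_out)
    return Path(fasta_out)
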