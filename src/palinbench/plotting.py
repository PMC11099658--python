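"""Plot helpers for the experiment tables (matplotlib)."""

from __future__ import annotations

import pandas as pd


def plot_score_distributions(df: pd.DataFrame, ax=None):
    """Overlaid score histograms, one per pairing, from an exp_score_shift
    (or mutation-gradient) table with columns ``pairing``/``target`` and
    ``score``."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    key = "pairing" if "pairing" in df.columns else "target"
    for name, grp in df.groupby(key, sort=False):
        ax.hist(grp.score, bins=40, histtype="step", density=True, label=str(name))
    ax.set_xlabel("Smith-Waterman score (half-bits)")
    ax.set_ylabel("density")
    ax.legend(fontsize=8)
    return ax


def plot_length_curves(df: pd.DataFrame, ax=None):
    """Mean LPS/LCS vs length with theory overlay, from exp_palindrome_curves
    or exp_digest_curves output."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    x = df["bin_mid"] if "bin_mid" in df.columns else 0.5 * (df.bin_lo + df.bin_hi)
    for col, style in [("mean_lps", "o-"), ("mean_lcs", "s-"),
                       ("mean_lps_shuffled", "^-"),
                       ("expected_lps", "--"), ("expected_lcs", ":")]:
        if col in df.columns:
            ax.plot(x, df[col], style, label=col, markersize=3)
    ax.set_xlabel("sequence length")
    ax.set_ylabel("substring length (residues)")
    ax.legend(fontsize=8)
    return ax
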