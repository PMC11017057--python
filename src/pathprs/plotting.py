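"""Small plotting helpers hanging off the results tables."""

from __future__ import annotations

import pandas as pd


def plot_meta_forest(meta_results: pd.DataFrame, pathway: str, ax=None):
    """Forest-style plot of pooled betas (95% CI) per phenotype/threshold
    for one pathway, mirroring the per-threshold dot display of pathway
    score association figures."""
    import matplotlib.pyplot as plt

    sub = meta_results[meta_results["pathway"] == pathway]
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 0.35 * max(len(sub), 4) + 1))
    labels = [f"{r.phenotype} @ {r.threshold:g}" for r in sub.itertuples()]
    y = range(len(sub))
    ax.errorbar(sub["beta"], list(y), xerr=1.96 * sub["se"], fmt="o", ms=3, capsize=2)
    ax.axvline(0.0, color="grey", lw=0.8)
    ax.set_yticks(list(y), labels, fontsize=7)
    ax.set_xlabel("pooled beta (Z per SD of score)")
    ax.set_title(f"{pathway} pathway score associations")
    return ax


def plot_h2(h2_table: pd.DataFrame, ax=None):
    """Point estimates with 95% CIs for every phenotype's SNP heritability."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    y = range(len(h2_table))
    err = [
        (h2_table["h2"] - h2_table["ci_low"]).clip(lower=0),
        (h2_table["ci_high"] - h2_table["h2"]).clip(lower=0),
    ]
    ax.errorbar(h2_table["h2"], list(y), xerr=err, fmt="s", ms=4, capsize=2)
    ax.set_yticks(list(y), h2_table["phenotype"], fontsize=8)
    ax.set_xlim(0, 1)
    ax.set_xlabel("SNP-based h2")
    return ax
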