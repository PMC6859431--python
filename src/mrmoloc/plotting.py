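"""Minimal plotting helpers: leave-one-out forest plot, MR volcano plot, and
stacked regional association panels for colocalized loci.

All functions take/return matplotlib axes and never call show(); use a
non-interactive backend in scripts.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def forest_plot(loo_table: pd.DataFrame, full_estimate: float, full_se: float, ax=None):
    """Leave-one-out forest plot from a pipeline leave-one-out table."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 0.4 * len(loo_table) + 1.5))
    y = np.arange(len(loo_table))[::-1]
    ax.errorbar(loo_table["b"], y, xerr=1.96 * loo_table["se"], fmt="o",
                color="black", capsize=2, markersize=4)
    ax.errorbar([full_estimate], [-1], xerr=[1.96 * full_se], fmt="D",
                color="firebrick", capsize=2, markersize=5)
    ax.axvline(0, color="grey", lw=0.8, ls="--")
    ax.set_yticks(list(y) + [-1])
    ax.set_yticklabels(list(loo_table["excluded_variant"]) + ["all instruments"])
    ax.set_xlabel("causal estimate (95% CI)")
    ax.set_title("leave-one-out sensitivity")
    return ax


def volcano_plot(mr_table: pd.DataFrame, bonferroni: float | None = None, ax=None):
    """Estimate vs -log10 p for an MR results table."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    ok = mr_table[mr_table["status"] == "ok"]
    ax.scatter(ok["b"], ok["neg_log10_pval"], s=14, c="steelblue")
    ax.axhline(-np.log10(0.05), color="black", lw=0.8, ls=":")
    if bonferroni is not None and bonferroni == bonferroni:
        ax.axhline(-np.log10(bonferroni), color="firebrick", lw=0.8, ls="--")
    ax.set_xlabel("causal estimate")
    ax.set_ylabel(r"$-\log_{10} p$")
    return ax


def regional_plot(region, labels=None, axes=None):
    """Stacked -log10 p panels, one per trait, over a region's variants."""
    import matplotlib.pyplot as plt

    labels = labels or region.labels
    if axes is None:
        _, axes = plt.subplots(len(labels), 1, sharex=True,
                               figsize=(6, 1.8 * len(labels)))
    pos = np.arange(region.n_variants)
    for ax, lab in zip(np.atleast_1d(axes), labels):
        logp = -np.log10(np.maximum(region.pvalues(lab), 1e-300))
        ax.scatter(pos, logp, s=10)
        ax.set_ylabel(f"{lab}: " + r"$-\log_{10} p$", fontsize=8)
    np.atleast_1d(axes)[-1].set_xlabel("variant index")
    return axes
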