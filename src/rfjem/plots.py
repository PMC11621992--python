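"""Minimal plotting helper: a forest plot of odds ratios per analysis cell."""

from __future__ import annotations

import numpy as np
import pandas as pd


def forest_plot(results: pd.DataFrame, ax=None, title: str | None = None):
    """Forest plot of OR rows (as produced by the pipeline's results table).

    Each row needs ``OR``, ``CI_low``, ``CI_high`` and a few identifying
    columns; non-converged rows are skipped.  Returns the matplotlib axes.
    """
    import matplotlib.pyplot as plt

    rows = results[results["converged"]].reset_index(drop=True)
    if rows.empty:
        raise ValueError("no converged rows to plot")
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 0.4 * len(rows) + 1.5))
    y = np.arange(len(rows))[::-1]
    ax.errorbar(
        rows["OR"], y,
        xerr=[rows["OR"] - rows["CI_low"], rows["CI_high"] - rows["OR"]],
        fmt="s", color="black", ecolor="gray", capsize=2, markersize=4,
    )
    ax.axvline(1.0, color="firebrick", lw=0.8, ls="--")
    labels = [
        "/".join(str(r[c]) for c in ("method", "label", "metric", "category")
                 if c in rows.columns)
        for _, r in rows.iterrows()
    ]
    ax.set_yticks(y)
    ax.set_yticklabels(labels, fontsize=8)
    ax.set_xscale("log")
    ax.set_xlabel("odds ratio (log scale)")
    if title:
        ax.set_title(title)
    return ax
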