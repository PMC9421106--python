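"""Predicted-versus-observed figures, one panel per prediction source.

Shaded channels mark absolute prediction deviances up to ±1, ±2 and ±3
percentage points; dotted lines mark the programmatic prevalence thresholds.
"""

from __future__ import annotations

import numpy as np

from .metrics import match_pairs, thresholds_for


def plot_predicted_vs_observed(predictions, observed, outcome, path=None):
    """Scatter ŷ vs y per source with deviance bands and threshold lines.

    Returns the matplotlib figure; saves to ``path`` when given.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    preds = predictions[predictions["outcome"] == outcome]
    obs = observed[observed["outcome"] == outcome]
    sources = sorted(preds["source"].unique())
    fig, axes = plt.subplots(1, len(sources), figsize=(4 * len(sources), 4),
                             squeeze=False)
    ts = thresholds_for(outcome)
    for ax, source in zip(axes[0], sources):
        pairs = match_pairs(preds[preds["source"] == source], obs)
        lim = max(0.05, float(pairs[["point", "y"]].to_numpy().max()) * 1.1)
        grid = np.linspace(0, lim, 50)
        for band, shade in ((0.03, 0.92), (0.02, 0.85), (0.01, 0.75)):
            ax.fill_between(grid, grid - band, grid + band,
                            color=str(shade), linewidth=0)
        ax.plot(grid, grid, color="k", linewidth=0.8)
        ax.scatter(pairs["y"], pairs["point"], s=14, color="tab:blue",
                   alpha=0.8, zorder=3)
        if ts is not None:
            for tau in (ts.lower, ts.upper):
                ax.axvline(tau, linestyle=":", color="k", linewidth=0.8)
                ax.axhline(tau, linestyle=":", color="k", linewidth=0.8)
        ax.set_xlim(0, lim)
        ax.set_ylim(0, lim)
        ax.set_xlabel("observed prevalence")
        ax.set_ylabel("predicted prevalence")
        ax.set_title(f"{outcome} — {source} (n={len(pairs)})")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
    return fig
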