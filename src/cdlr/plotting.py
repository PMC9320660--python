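"""Incidence-vs-dose figure: binned toxicity proportions with the fitted sigmoid."""

from __future__ import annotations

import numpy as np

from .binning import BinnedSeries
from .model import CDLRParams, ntcp


def plot_fit(series: BinnedSeries, params: CDLRParams, ax=None, n_curve: int = 200):
    """Scatter the per-bin incidences (marker area ~ bin count) and overlay
    the fitted CDLR curve.  Returns the matplotlib Axes."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    if series.bins:
        d = np.array([b.dose_rep for b in series.bins])
        p = np.array([b.incidence for b in series.bins])
        w = np.array([b.n_total for b in series.bins], dtype=float)
        ax.scatter(d, p, s=20 * w, alpha=0.7, label="bin incidence")
        lo, hi = series.bins[0].lower, series.bins[-1].upper
    else:
        lo, hi = 0.0, 80.0
    grid = np.linspace(max(lo, 0.0), hi, n_curve)
    ax.plot(grid, ntcp(grid, params), "r-", label="fitted CDLR curve")
    ax.set_xlabel(f"{series.metric} inner-ear dose (Gy)")
    ax.set_ylabel("toxicity incidence")
    ax.set_ylim(-0.05, 1.05)
    ax.legend()
    return ax
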