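"""Dot plots of per-cell ratios by condition (matplotlib hooks)."""

from __future__ import annotations

import numpy as np


def dot_plot(condition_values: dict, ax=None, ylabel: str = "normalized G/R",
             jitter: float = 0.08, seed: int = 0):
    """One jittered dot per cell, grouped by condition, with median bars.

    ``condition_values`` maps condition label -> sequence of per-cell
    values.  Returns the matplotlib Axes.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(1.2 * max(len(condition_values), 2), 4))
    rng = np.random.default_rng(seed)
    labels = list(condition_values)
    for i, lab in enumerate(labels):
        v = np.asarray(condition_values[lab], dtype=float)
        v = v[np.isfinite(v)]
        x = i + rng.uniform(-jitter, jitter, size=v.size)
        ax.plot(x, v, "o", ms=4, alpha=0.6)
        if v.size:
            ax.hlines(np.median(v), i - 0.25, i + 0.25, color="k", lw=2)
    ax.set_xticks(range(len(labels)), [str(l) for l in labels])
    ax.set_ylabel(ylabel)
    return ax
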