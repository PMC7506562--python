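"""Minimal plotting helpers: synchrony traces and zone heatmaps.

Presentation only — every quantity plotted here is computed by the
analysis modules.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .geometry import LAT_LABELS, LONG_LABELS
from .synchrony import SynchronySeries


def plot_synchrony(sync: SynchronySeries, ax=None):
    """Line plot of r'(t) over the concatenated match frames."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(10, 3))
    r = sync.data["r_prime"].to_numpy()
    ax.plot(np.arange(len(r)), r, lw=0.6)
    ax.set_ylim(0, 1.02)
    ax.set_xlabel("frame")
    ax.set_ylabel("r'")
    ax.set_title(f"synchronization, {sync.team} team")
    return ax


def plot_zone_means(zone_table: pd.DataFrame, ax=None):
    """Heatmap of mean r' on the 20-cell pitch grid (rows D→O, cols L→R)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    data = zone_table.reindex(index=list(LONG_LABELS), columns=list(LAT_LABELS))
    im = ax.imshow(data.to_numpy(dtype=float).T, cmap="coolwarm", vmin=0, vmax=1)
    ax.set_xticks(range(len(LONG_LABELS)), LONG_LABELS)
    ax.set_yticks(range(len(LAT_LABELS)), LAT_LABELS)
    ax.figure.colorbar(im, ax=ax, label="mean r'")
    return ax
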