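"""Heat maps of causal graphs and grid maps of localization results."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .causal import CausalGraph
from .recordings import GridLayout

__all__ = ["plot_graph_heatmap", "plot_grid_map"]


def plot_graph_heatmap(graph: CausalGraph, ax=None, title: str | None = None):
    """Heat map of the pairwise causal-influence matrix (row i drives col j)."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4.2))
    im = ax.imshow(graph.weights, cmap="viridis", aspect="equal")
    ax.set_xlabel("influenced node j")
    ax.set_ylabel("influencing node i")
    if title:
        ax.set_title(title)
    plt.colorbar(im, ax=ax, label=f"{graph.measure.upper()} weight")
    return ax


def plot_grid_map(
    grid: GridLayout,
    eoi=(),
    inferred=(),
    ax=None,
    title: str | None = None,
):
    """Electrode-grid map: EOI drawn as bold annuli, inferred nodes as solid dots."""
    if ax is None:
        _, ax = plt.subplots(figsize=(1.0 + 0.7 * grid.n_cols, 1.0 + 0.7 * grid.n_rows))
    eoi, inferred = set(eoi), set(inferred)
    for r in range(grid.n_rows):
        for c in range(grid.n_cols):
            lab = grid.label_of(r, c)
            y = grid.n_rows - 1 - r
            ax.plot(c, y, "o", ms=16, mfc="none", mec="0.7", mew=1)
            if lab in eoi:
                ax.plot(c, y, "o", ms=20, mfc="none", mec="black", mew=2.5)
            if lab in inferred:
                ax.plot(c, y, "o", ms=10, color="#8b4513")
            ax.annotate(lab, (c, y), (0, -14), textcoords="offset points",
                        ha="center", fontsize=7)
    ax.set_xlim(-0.8, grid.n_cols - 0.2)
    ax.set_ylim(-0.9, grid.n_rows - 0.1)
    ax.set_aspect("equal")
    ax.axis("off")
    if title:
        ax.set_title(title)
    return ax
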