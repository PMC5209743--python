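"""Heat-map rendering of descriptor statistics.

Descriptor grids are drawn as 13 features x 8 (statistic, distance)
columns, matching the canonical descriptor order.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .texture import DISTANCES, FEATURE_NAMES, STAT_NAMES


def _grid_from_vector(values: pd.Series) -> np.ndarray:
    """Reshape a canonical 104-vector to a 13 x 8 (feature x stat/dist) grid."""
    grid = np.empty((len(FEATURE_NAMES), len(STAT_NAMES) * len(DISTANCES)))
    for fi, feat in enumerate(FEATURE_NAMES):
        col = 0
        for stat in STAT_NAMES:
            for d in DISTANCES:
                grid[fi, col] = values[f"{feat}_{stat}_d{d}"]
                col += 1
    return grid


def plot_pvalue_heatmap(pvalues: pd.Series, path, annotate=(0.05, 0.15)):
    """Render the 104 t-test p-values as a feature x statistic grid.

    ``annotate`` levels are drawn as contour annotations only; no p-value
    filtering is applied.
    """
    grid = _grid_from_vector(pvalues)
    fig, ax = plt.subplots(figsize=(8, 6))
    im = ax.imshow(grid, cmap="viridis_r", vmin=0, vmax=1, aspect="auto")
    ax.set_yticks(range(len(FEATURE_NAMES)), FEATURE_NAMES, fontsize=7)
    ax.set_xticks(
        range(len(STAT_NAMES) * len(DISTANCES)),
        [f"{s}_d{d}" for s in STAT_NAMES for d in DISTANCES],
        rotation=45,
        fontsize=7,
    )
    for fi in range(grid.shape[0]):
        for ci in range(grid.shape[1]):
            if grid[fi, ci] < min(annotate):
                ax.text(ci, fi, "*", ha="center", va="center", color="w")
    fig.colorbar(im, ax=ax, label="p-value")
    fig.tight_layout()
    fig.savefig(Path(path), dpi=150)
    plt.close(fig)


def plot_condition_heatmap(norm: pd.DataFrame, path):
    """Render min-max normalized condition-mean descriptors (conditions x 104)."""
    fig, ax = plt.subplots(figsize=(12, 3 + 0.3 * len(norm)))
    im = ax.imshow(norm.to_numpy(), cmap="coolwarm", vmin=0, vmax=1, aspect="auto")
    ax.set_yticks(range(len(norm)), norm.index, fontsize=8)
    ax.set_xlabel("descriptor (canonical order)")
    fig.colorbar(im, ax=ax, label="normalized value")
    fig.tight_layout()
    fig.savefig(Path(path), dpi=150)
    plt.close(fig)
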