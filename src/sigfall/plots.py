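"""Simple descriptive plots: effect-size radar and correlation heatmap."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

__all__ = ["plot_effect_radar", "plot_correlation_heatmap"]


def plot_effect_radar(comparison: pd.DataFrame, path: str | Path) -> Path:
    """Radar plot of per-feature standardised group differences (z_effect)."""
    names = list(comparison.index)
    z = comparison["z_effect"].to_numpy()
    angles = np.linspace(0, 2 * np.pi, len(names), endpoint=False)
    fig, ax = plt.subplots(subplot_kw={"polar": True}, figsize=(8, 8))
    ax.plot(np.r_[angles, angles[:1]], np.r_[z, z[:1]], lw=1.5)
    ax.fill(np.r_[angles, angles[:1]], np.r_[z, z[:1]], alpha=0.25)
    ax.set_xticks(angles)
    ax.set_xticklabels(names, fontsize=6)
    ax.set_title("Faller - non-faller difference (non-faller SD units)")
    path = Path(path)
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
    return path


def plot_correlation_heatmap(corr: pd.DataFrame, path: str | Path) -> Path:
    """Heatmap of the inter-characteristic correlation matrix."""
    fig, ax = plt.subplots(figsize=(9, 8))
    im = ax.imshow(corr.to_numpy(), vmin=-1, vmax=1, cmap="RdBu")
    ax.set_xticks(range(len(corr.columns)))
    ax.set_xticklabels(corr.columns, rotation=90, fontsize=6)
    ax.set_yticks(range(len(corr.index)))
    ax.set_yticklabels(corr.index, fontsize=6)
    fig.colorbar(im, ax=ax, label="Pearson r")
    path = Path(path)
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
    return path
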