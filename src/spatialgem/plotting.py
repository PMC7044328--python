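"""Minimal matplotlib helpers for the pipeline's standard figures."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

__all__ = ["plot_robustness_curve", "plot_enrichment_heatmap", "plot_spatial_gene"]


def plot_robustness_curve(curve, path: str | Path) -> None:
    """Forced-flux fraction vs growth (% of max), one panel."""
    fig, ax = plt.subplots(figsize=(4, 3))
    ax.plot(100 * curve.fractions, curve.growth_pct, marker="o", ms=3)
    ax.set_xlabel(f"{curve.reaction} flux (% of max feasible)")
    ax.set_ylabel("growth (% of max)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_enrichment_heatmap(frames: dict[str, pd.DataFrame], path: str | Path) -> None:
    """−log10 p heatmap, pathways × sections (columns = section labels)."""
    pathways = sorted({p for df in frames.values() for p in df.index})
    mat = np.zeros((len(pathways), len(frames)))
    for j, (_, df) in enumerate(frames.items()):
        for i, p in enumerate(pathways):
            if p in df.index:
                mat[i, j] = df.loc[p, "neg_log10_p"]
    fig, ax = plt.subplots(figsize=(2 + 0.8 * len(frames), 1 + 0.3 * len(pathways)))
    im = ax.imshow(mat, aspect="auto", cmap="Reds")
    ax.set_xticks(range(len(frames)), labels=list(frames))
    ax.set_yticks(range(len(pathways)), labels=pathways, fontsize=7)
    fig.colorbar(im, label="-log10 p")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_spatial_gene(
    coords: np.ndarray, values: Sequence[float], path: str | Path, title: str = ""
) -> None:
    """Spot scatter colored by (log-normalized) expression."""
    fig, ax = plt.subplots(figsize=(4, 4))
    sc = ax.scatter(coords[:, 0], coords[:, 1], c=list(values), s=18, cmap="RdBu_r")
    ax.set_aspect("equal")
    ax.set_xlabel("x (um)")
    ax.set_ylabel("y (um)")
    if title:
        ax.set_title(title)
    fig.colorbar(sc, label="log2 normalized expression")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
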