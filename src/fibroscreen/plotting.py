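"""Optional figures: similarity heatmaps and normalized time courses."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from .profiling import SimilarityMatrix

__all__ = ["plot_similarity_heatmap", "plot_timecourse"]


def plot_similarity_heatmap(
    similarity: SimilarityMatrix, path: Path | str, title: str = ""
) -> None:
    """Clustered treatment-similarity heatmap (green positive, magenta negative)."""
    r = similarity.reordered()
    fig, ax = plt.subplots(figsize=(0.4 * len(r) + 2.5,) * 2)
    im = ax.imshow(r.to_numpy(), cmap="PiYG", vmin=-1, vmax=1)
    ax.set_xticks(range(len(r)), r.columns, rotation=90, fontsize=7)
    ax.set_yticks(range(len(r)), r.index, fontsize=7)
    fig.colorbar(im, ax=ax, label="Pearson r", shrink=0.8)
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_timecourse(
    points: pd.DataFrame, path: Path | str, value: str = "fibrosis_norm"
) -> None:
    """Mean +/- SEM of a normalized readout per treatment over days."""
    fig, ax = plt.subplots(figsize=(6, 4))
    for treatment, sub in points.groupby("treatment"):
        agg = sub.groupby("day")[value].agg(["mean", "sem"])
        ax.errorbar(
            agg.index, agg["mean"], yerr=agg["sem"], marker="o",
            capsize=3, label=treatment,
        )
    ax.axhline(1.0, color="grey", lw=0.8, ls="--")
    ax.set_xlabel("day")
    ax.set_ylabel(f"{value} (fold vs control)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
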