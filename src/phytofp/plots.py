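"""Figure rendering for comparison results.

All plotting is a side effect of already-computed tables and result objects;
nothing downstream reads a figure.  Uses the Agg backend so rendering works
headless.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import seaborn as sns

from .comparative import HcaResult, PcaResult, SpeciesProfile, VennResult

__all__ = [
    "plot_superclass_pies",
    "plot_venn_counts",
    "plot_pca_scores",
    "plot_dendrogram",
    "plot_heatmap",
]


def plot_superclass_pies(profiles: Sequence[SpeciesProfile], path: str | Path) -> None:
    """One pie of superclass shares per species."""
    fig, axes = plt.subplots(1, len(profiles), figsize=(4.2 * len(profiles), 4.2))
    axes = np.atleast_1d(axes)
    for ax, profile in zip(axes, profiles):
        counts: dict[str, int] = {}
        for c in profile.compounds:
            sc = c.superclass or "Unclassified"
            counts[sc] = counts.get(sc, 0) + 1
        ordered = sorted(counts.items(), key=lambda kv: -kv[1])
        ax.pie([v for _, v in ordered],
               labels=[k for k, _ in ordered], textprops={"fontsize": 7})
        ax.set_title(profile.species)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_venn_counts(venn: VennResult, path: str | Path) -> None:
    """Horizontal bar chart of membership-region counts (an UpSet-style view;
    a 4-ellipse diagram does not add information over the counts)."""
    frame = venn.to_frame()
    fig, ax = plt.subplots(figsize=(7, 0.35 * len(frame) + 1.5))
    ax.barh(frame["region"], frame["count"], color="#4c72b0")
    ax.set_xlabel("compounds in region")
    ax.invert_yaxis()
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_pca_scores(result: PcaResult, sample_species: Sequence[str],
                    path: str | Path) -> None:
    fig, ax = plt.subplots(figsize=(5.5, 4.5))
    species = list(dict.fromkeys(sample_species))
    palette = sns.color_palette("deep", len(species))
    for sp, color in zip(species, palette):
        idx = [i for i, s in enumerate(sample_species) if s == sp]
        ax.scatter(result.scores[idx, 0], result.scores[idx, 1],
                   label=sp, color=color, s=45)
    ev = result.explained_variance_pct
    ax.set_xlabel(f"PC1 ({ev[0]:.1f}%)")
    ax.set_ylabel(f"PC2 ({ev[1]:.1f}%)" if len(ev) > 1 else "PC2")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_dendrogram(result: HcaResult, path: str | Path) -> None:
    fig, ax = plt.subplots(figsize=(6, 4))
    sch.dendrogram(result.linkage_matrix, labels=result.labels,
                   orientation="right", ax=ax)
    ax.set_xlabel("Euclidean distance")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_heatmap(counts: pd.DataFrame, path: str | Path) -> None:
    """Clustered superclass x replicate heatmap (Euclidean, average linkage)."""
    grid = sns.clustermap(
        counts,
        method="average",
        metric="euclidean",
        cmap="RdBu",
        figsize=(8, 6),
        dendrogram_ratio=0.15,
    )
    grid.savefig(path)
    plt.close(grid.figure)
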