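"""Optional matplotlib figures: heatmap, dendrogram, and network diagram.

Imported lazily by the CLI's ``--plots`` flag; the analysis never depends
on these.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import scipy.cluster.hierarchy as sch

from .idiographic import ClusterTree, DistanceMatrix, SymptomNetwork, ward_cluster
from .catalog import LABEL


def _plt():
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    return plt


def heatmap(D: DistanceMatrix, path: str | Path, tree: ClusterTree | None = None) -> None:
    """Distance-matrix heatmap ordered by dendrogram leaf order."""
    plt = _plt()
    tree = tree or ward_cluster(D)
    order = [D.items.index(i) for i in tree.leaf_order()]
    values = D.values[np.ix_(order, order)]
    labels = [LABEL[D.items[i]] for i in order]
    fig, ax = plt.subplots(figsize=(7, 6))
    im = ax.imshow(values, cmap="RdBu")
    ax.set_xticks(range(len(labels)), labels, rotation=90, fontsize=7)
    ax.set_yticks(range(len(labels)), labels, fontsize=7)
    fig.colorbar(im, ax=ax, label="DTW distance")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def dendrogram(tree: ClusterTree, path: str | Path) -> None:
    plt = _plt()
    fig, ax = plt.subplots(figsize=(7, 4))
    sch.dendrogram(
        tree.to_linkage(), labels=[LABEL[i] for i in tree.items], ax=ax,
        leaf_rotation=90, leaf_font_size=7,
    )
    ax.set_ylabel("merge height")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def network(net: SymptomNetwork, path: str | Path) -> None:
    """Circular-layout network; edge width proportional to similarity."""
    plt = _plt()
    n = len(net.items)
    theta = 2 * np.pi * np.arange(n) / n
    xy = np.column_stack([np.cos(theta), np.sin(theta)])
    fig, ax = plt.subplots(figsize=(6, 6))
    for a in range(n):
        for b in range(a + 1, n):
            w = net.weights[a, b]
            if w <= 0:
                continue
            ax.plot(*zip(xy[a], xy[b]), color="steelblue", alpha=0.7, lw=2.5 * w, zorder=1)
    ax.scatter(xy[:, 0], xy[:, 1], s=400, c="white", edgecolors="black", zorder=2)
    for (x, y), item in zip(xy, net.items):
        ax.annotate(str(item), (x, y), ha="center", va="center", fontsize=8, zorder=3)
    ax.set_axis_off()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
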