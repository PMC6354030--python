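"""Downstream artifacts: Ward clustering of the distance matrix and
thresholded similarity edge lists.

Ward linkage is applied to the distance matrix directly (acknowledging Ward's
Euclidean assumption); similarity is defined as 1 - distance, and edges below
the similarity threshold (default 0.30) are dropped.
"""
from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .distance import DistanceMatrix
from .errors import ConfigError


@dataclass
class Dendrogram:
    """Ward merge tree over the sample roster (scipy linkage encoding)."""

    sample_ids: list[str]
    linkage: np.ndarray  # (n-1, 4) scipy linkage matrix

    def leaves(self) -> list[str]:
        order = hierarchy.leaves_list(self.linkage)
        return [self.sample_ids[i] for i in order]

    def to_newick(self) -> str:
        """Newick string with branch lengths from merge heights (leaves at 0)."""
        n = len(self.sample_ids)
        heights = {i: 0.0 for i in range(n)}

        def node_str(i: int, parent_height: float) -> str:
            if i < n:
                name = self.sample_ids[i]
                return f"{name}:{parent_height - heights[i]:.10g}"
            row = self.linkage[i - n]
            left, right = int(row[0]), int(row[1])
            h = float(row[2])
            inner = f"({node_str(left, h)},{node_str(right, h)})"
            return f"{inner}:{parent_height - h:.10g}"

        for i in range(self.linkage.shape[0]):
            heights[n + i] = float(self.linkage[i, 2])
        root = n + self.linkage.shape[0] - 1
        row = self.linkage[-1]
        h = float(row[2])
        return f"({node_str(int(row[0]), h)},{node_str(int(row[1]), h)});"

    def save_newick(self, path: str | os.PathLike) -> None:
        with open(path, "wt", encoding="ascii") as fh:
            fh.write(self.to_newick() + "\n")


def ward_cluster(m: DistanceMatrix) -> Dendrogram:
    """Agglomerative clustering with Ward linkage on the distance matrix."""
    if len(m.sample_ids) < 2:
        raise ConfigError("clustering requires at least 2 samples")
    condensed = squareform(m.values, checks=False)
    linkage = hierarchy.linkage(condensed, method="ward")
    return Dendrogram(list(m.sample_ids), linkage)


def similarity_edges(
    m: DistanceMatrix, threshold: float = 0.30
) -> list[tuple[str, str, float]]:
    """(a, b, 1 - d) triples with similarity >= threshold, descending similarity.

    Ties break by roster order; self-edges are never included.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ConfigError(f"similarity threshold must be in [0, 1], got {threshold}")
    ids = m.sample_ids
    edges = []
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            sim = 1.0 - float(m.values[i, j])
            if sim >= threshold:
                edges.append((ids[i], ids[j], sim))
    edges.sort(key=lambda e: (-e[2], ids.index(e[0]), ids.index(e[1])))
    return edges


def write_edges_tsv(
    edges: Sequence[tuple[str, str, float]], path: str | os.PathLike
) -> None:
    with open(path, "wt", encoding="ascii") as fh:
        fh.write("sample_a\tsample_b\tsimilarity\n")
        for a, b, sim in edges:
            fh.write(f"{a}\t{b}\t{sim:.12g}\n")


def plot_heatmap(
    m: DistanceMatrix,
    path: str | os.PathLike,
    dendrogram: Dendrogram | None = None,
) -> None:
    """Distance heatmap on a fixed [0, 1] scale, ordered by dendrogram leaves."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ids = list(m.sample_ids)
    order = list(range(len(ids)))
    if dendrogram is not None:
        leaf_ids = dendrogram.leaves()
        order = [ids.index(s) for s in leaf_ids]
    vals = m.values[np.ix_(order, order)]
    labels = [ids[i] for i in order]
    fig, ax = plt.subplots(figsize=(max(4, 0.4 * len(ids)), max(3.5, 0.4 * len(ids))))
    im = ax.imshow(vals, vmin=0.0, vmax=1.0, cmap="RdYlGn_r")
    ax.set_xticks(range(len(labels)), labels, rotation=90, fontsize=7)
    ax.set_yticks(range(len(labels)), labels, fontsize=7)
    fig.colorbar(im, ax=ax, label="distance")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
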