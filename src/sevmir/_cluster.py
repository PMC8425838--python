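"""Shared hierarchical-clustering helpers: deterministic average linkage on a
precomputed distance matrix, a reproducible leaf order, and Newick export.

Leaf ordering rule: at every merge the subtree whose minimum original leaf
index is smaller is placed first.  This makes dendrograms reproducible across
platforms regardless of tie-breaking inside the linkage routine.

Newick branch lengths follow the ultrametric convention used by R's
``ape::as.phylo.hclust``: node heights are half the merge distance, so the
path length between two leaves equals the distance at which they merge.
"""

from __future__ import annotations

import numpy as np
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform


def average_linkage(distances: np.ndarray) -> np.ndarray:
    """Average (UPGMA) linkage on a square symmetric distance matrix."""
    d = np.asarray(distances, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("average_linkage: square distance matrix required")
    return linkage(squareform(d, checks=False), method="average")


def _subtree(node: int, n: int, Z: np.ndarray, cache: dict) -> tuple[int, list[int]]:
    """Return (min original index, ordered leaf list) for a node id."""
    if node in cache:
        return cache[node]
    if node < n:
        out = (node, [node])
    else:
        a, b = int(Z[node - n, 0]), int(Z[node - n, 1])
        min_a, leaves_a = _subtree(a, n, Z, cache)
        min_b, leaves_b = _subtree(b, n, Z, cache)
        if min_b < min_a:
            (min_a, leaves_a), (min_b, leaves_b) = (min_b, leaves_b), (min_a, leaves_a)
        out = (min_a, leaves_a + leaves_b)
    cache[node] = out
    return out


def leaf_order(Z: np.ndarray, n: int) -> list[int]:
    """Deterministic leaf ordering (smaller minimum original index first)."""
    if n == 1:
        return [0]
    _, leaves = _subtree(2 * n - 2, n, Z, {})
    return leaves


def to_newick(Z: np.ndarray, labels: list[str]) -> str:
    """Serialize a linkage tree as a Newick string with ultrametric lengths."""
    n = len(labels)
    if n == 1:
        return f"{labels[0]};"
    heights = {i: 0.0 for i in range(n)}
    for i in range(len(Z)):
        heights[n + i] = float(Z[i, 2]) / 2.0

    cache: dict = {}

    def render(node: int) -> str:
        if node < n:
            return labels[node]
        a, b = int(Z[node - n, 0]), int(Z[node - n, 1])
        if _subtree(b, n, Z, cache)[0] < _subtree(a, n, Z, cache)[0]:
            a, b = b, a
        parts = []
        for child in (a, b):
            bl = heights[node] - heights[child]
            parts.append(f"{render(child)}:{bl:.10g}")
        return "(" + ",".join(parts) + ")"

    return render(2 * n - 2) + ";"
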