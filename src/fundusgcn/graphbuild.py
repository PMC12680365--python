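"""Batch-graph construction from feature vectors.

Each mini-batch of images becomes a graph: nodes are the samples'
pooled feature vectors and edges connect similar samples under the
combined distance

    d_comb(i, j) = beta * d_sp(i, j) + (1 - beta) * d_se(i, j)

where ``d_sp`` is a magnitude-sensitive spatial distance (Euclidean by
default) and ``d_se`` a direction-sensitive semantic distance (cosine by
default).  Both matrices are min-max normalised to [0, 1] per batch so
the radius threshold is scale-free.  The edge set consists of

* a self-loop on every node (guaranteeing deg(i) >= 1), and
* mutual k-nearest-neighbour pairs (i in j's top-k and j in i's top-k
  under d_comb) whose normalised d_comb is within ``radius``, the
  threshold for edge creation.

Mutual selection plus the radius cut keeps the batch graph sparse and
its neighbourhoods pure: with one-sided k-NN linking, node degrees grow
to the point where the degree-normalised aggregation gives each node
only a small weight on its own features, and samples of adjacent
severity grades blur into one another.  Enlarging k or the radius can
only add edges, never remove one.  k-NN ties are broken by ascending
node index, making construction fully deterministic for a given
feature matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial.distance import cdist

__all__ = [
    "BatchGraph",
    "pairwise_distances",
    "combined_distance",
    "build_graph",
    "normalized_adjacency",
]

_METRICS = ("euclidean", "cosine")


@dataclass
class BatchGraph:
    """Undirected weighted graph over one batch of samples."""

    n: int
    edges: dict[tuple[int, int], float]  # key (i, j) with i <= j; includes self-loops
    degrees: np.ndarray  # deg(i) = number of incident edges incl. the self-loop
    beta: float
    k: int
    radius: float
    ids: list[str] = field(default_factory=list)

    def has_edge(self, i: int, j: int) -> bool:
        a, b = (i, j) if i <= j else (j, i)
        return (a, b) in self.edges

    def adjacency(self) -> np.ndarray:
        """Dense symmetric 0/1 adjacency (self-loops on the diagonal)."""
        a = np.zeros((self.n, self.n))
        for (i, j) in self.edges:
            a[i, j] = 1.0
            a[j, i] = 1.0
        return a

    def dump_edgelist(self, path: str | Path) -> None:
        """Debug dump: one ``i j weight`` line per edge, 0-based indices."""
        lines = [
            f"{i} {j} {w:.10g}" for (i, j), w in sorted(self.edges.items())
        ]
        Path(path).write_text("\n".join(lines) + "\n")


def _minmax(d: np.ndarray) -> np.ndarray:
    lo, hi = d.min(), d.max()
    if hi > lo:
        return (d - lo) / (hi - lo)
    return np.zeros_like(d)


def pairwise_distances(
    features: np.ndarray,
    spatial_metric: str = "euclidean",
    semantic_metric: str = "cosine",
) -> tuple[np.ndarray, np.ndarray]:
    """Spatial and semantic distance matrices, min-max normalised to [0,1].

    Both are symmetric with a zero diagonal.  Cosine distance of a
    zero-norm vector is defined as the maximum (1 before normalisation).
    """
    z = np.asarray(features, dtype=np.float64)
    if z.ndim != 2:
        raise ValueError(f"features must be (n, d), got {z.shape}")
    if not np.isfinite(z).all():
        raise ValueError("features contain non-finite entries")
    for m in (spatial_metric, semantic_metric):
        if m not in _METRICS:
            raise ValueError(f"unknown metric {m!r}; choose from {_METRICS}")
    n = z.shape[0]
    if n == 1:
        zero = np.zeros((1, 1))
        return zero, zero.copy()

    def _dist(metric: str) -> np.ndarray:
        if metric == "euclidean":
            d = cdist(z, z, metric="euclidean")
        else:
            norms = np.linalg.norm(z, axis=1)
            safe = np.where(norms > 0, norms, 1.0)
            cos = (z @ z.T) / np.outer(safe, safe)
            d = 1.0 - np.clip(cos, -1.0, 1.0)
            bad = norms == 0
            if bad.any():
                d[bad, :] = 1.0
                d[:, bad] = 1.0
        np.fill_diagonal(d, 0.0)
        d = 0.5 * (d + d.T)
        return _minmax(d)

    return _dist(spatial_metric), _dist(semantic_metric)


def combined_distance(d_sp, d_se, beta: float):
    """Eq-style convex combination beta*d_sp + (1-beta)*d_se."""
    if not 0.0 <= beta <= 1.0:
        raise ValueError(f"beta must be in [0, 1], got {beta}")
    d_sp = np.asarray(d_sp, dtype=np.float64)
    d_se = np.asarray(d_se, dtype=np.float64)
    if not (np.isfinite(d_sp).all() and np.isfinite(d_se).all()):
        raise ValueError("distances must be finite")
    if (d_sp < 0).any() or (d_se < 0).any():
        raise ValueError("distances must be non-negative")
    return beta * d_sp + (1.0 - beta) * d_se


def build_graph(
    features: np.ndarray,
    beta: float = 0.5,
    k: int = 4,
    radius: float = 0.1,
    ids: list[str] | None = None,
    spatial_metric: str = "euclidean",
    semantic_metric: str = "cosine",
) -> BatchGraph:
    """Construct the batch graph from pooled feature vectors.

    An undirected edge joins i and j when each is among the other's k
    nearest neighbours under d_comb *and* their normalised combined
    distance is within ``radius``; every node additionally carries a
    self-loop.  ``k`` is clamped to n-1 when the batch is small; a
    negative radius is rejected.  Edge weights store the combined
    distance d_comb.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if radius < 0:
        raise ValueError(f"radius must be >= 0, got {radius}")
    z = np.asarray(features, dtype=np.float64)
    if z.ndim == 1:
        z = z[None, :]
    n = z.shape[0]
    d_sp, d_se = pairwise_distances(z, spatial_metric, semantic_metric)
    d = combined_distance(d_sp, d_se, beta)

    edges: dict[tuple[int, int], float] = {(i, i): 0.0 for i in range(n)}
    kk = min(k, n - 1)
    if kk > 0 and n > 1:
        knn = np.zeros((n, n), dtype=bool)
        for i in range(n):
            order = np.lexsort((np.arange(n), d[i]))  # distance, then index
            neighbors = [j for j in order if j != i][:kk]
            knn[i, neighbors] = True
        mutual = knn & knn.T & (d <= radius)
        ii, jj = np.nonzero(np.triu(mutual, k=1))
        for a, b in zip(ii.tolist(), jj.tolist()):
            edges[(a, b)] = d[a, b]

    degrees = np.zeros(n, dtype=np.int64)
    for (i, j) in edges:
        degrees[i] += 1
        if j != i:
            degrees[j] += 1
    return BatchGraph(
        n=n,
        edges=edges,
        degrees=degrees,
        beta=beta,
        k=k,
        radius=radius,
        ids=list(ids) if ids is not None else [str(i) for i in range(n)],
    )


def normalized_adjacency(graph: BatchGraph, weighted: bool = False) -> np.ndarray:
    """S with S_ij = 1/sqrt(deg(i) deg(j)) on edges (incl. self-loops), else 0.

    This is the aggregation operator of the degree-normalised GCN update;
    every node has a self-loop so no entry divides by zero.  With
    ``weighted=True`` each edge entry is additionally scaled by the
    affinity 1 - d_comb (self-loops keep affinity 1); the unweighted
    form is the reference behaviour.
    """
    inv_sqrt = 1.0 / np.sqrt(graph.degrees.astype(np.float64))
    s = graph.adjacency()
    if weighted:
        for (i, j), w in graph.edges.items():
            a = max(0.0, 1.0 - w)
            s[i, j] = a
            s[j, i] = a
    return s * np.outer(inv_sqrt, inv_sqrt)
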