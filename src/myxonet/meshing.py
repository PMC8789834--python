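"""Stage-one output: the p_m-nearest-neighbour proximity mesh.

The mesh is an undirected weighted graph over the food sources plus the
sampled trail points: each point is connected to its p_m closest
neighbours (p_m = 10 in the standard conditions) and the directed
relation is symmetrised by union, giving the dense, site-responsive
lattice that the shortest-walk refinement carves networks out of.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import coo_matrix, csr_matrix
from scipy.spatial import cKDTree

_DEDUP_TOL = 1e-9
_EXACT_SORT_MAX = 4096  # below this, exact stable-sort k-NN (index tie-break)


@dataclass
class Mesh:
    """Weighted undirected proximity graph over trail points + sources.

    Nodes 0..n_sources-1 are the food sources (in layout order);
    the remaining nodes are trail points.  Edge weights are Euclidean
    lengths in pixels.
    """

    points: np.ndarray  # (N, 2)
    n_sources: int
    edges: np.ndarray  # (E, 2) int, u < v
    weights: np.ndarray  # (E,) pixels
    p_m: int
    _adj: csr_matrix | None = field(default=None, repr=False, compare=False)

    @property
    def n_nodes(self) -> int:
        return len(self.points)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def source_ids(self) -> np.ndarray:
        return np.arange(self.n_sources)

    @property
    def roles(self) -> np.ndarray:
        r = np.full(self.n_nodes, "trail", dtype=object)
        r[: self.n_sources] = "source"
        return r

    def adjacency(self) -> csr_matrix:
        """Symmetric sparse adjacency with edge lengths as weights."""
        if self._adj is None:
            u, v = self.edges[:, 0], self.edges[:, 1]
            n = self.n_nodes
            a = coo_matrix(
                (np.concatenate([self.weights, self.weights]),
                 (np.concatenate([u, v]), np.concatenate([v, u]))),
                shape=(n, n),
            )
            self._adj = a.tocsr()
        return self._adj

    def edge_set(self) -> set[tuple[int, int]]:
        return {(int(u), int(v)) for u, v in self.edges}


def _dedupe(points: np.ndarray) -> np.ndarray:
    """Merge points closer than the dedup tolerance (first occurrence wins).

    Sources come first in the array, so a trail sample coinciding with a
    source merges into the source node.
    """
    key = np.round(points / _DEDUP_TOL).astype(np.int64)
    _, keep = np.unique(key, axis=0, return_index=True)
    keep.sort()
    return points[keep] if len(keep) < len(points) else points


def _knn_exact(points: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """k nearest neighbours by full stable sort; ties to the smaller index."""
    d = np.linalg.norm(points[:, None, :] - points[None, :, :], axis=2)
    np.fill_diagonal(d, np.inf)
    order = np.argsort(d, axis=1, kind="stable")[:, :k]
    return order, np.take_along_axis(d, order, axis=1)


def build_mesh(
    points: np.ndarray,
    n_sources: int = 0,
    p_m: int = 10,
    dedupe: bool = True,
) -> Mesh:
    """Connect every point to its p_m closest neighbours (union-symmetrised).

    ``points`` holds the food sources first (``n_sources`` rows), then
    the trail samples.  Near-duplicate coordinates are merged before the
    neighbour search; k is truncated to N-1 for tiny inputs.
    """
    pts = np.asarray(points, dtype=float)
    if p_m < 1:
        raise ValueError("p_m must be >= 1")
    if dedupe:
        pts = _dedupe(pts)
    n = len(pts)
    if n < 2:
        raise ValueError("mesh needs at least 2 distinct points")
    k = min(p_m, n - 1)

    if n <= _EXACT_SORT_MAX:
        nbr, dist = _knn_exact(pts, k)
    else:
        tree = cKDTree(pts)
        dist, nbr = tree.query(pts, k=k + 1)
        # drop the self column (distance 0 in the first slot)
        dist, nbr = dist[:, 1:], nbr[:, 1:]

    src = np.repeat(np.arange(n), k)
    dst = nbr.ravel()
    w = dist.ravel()
    u = np.minimum(src, dst)
    v = np.maximum(src, dst)
    # union-symmetrise and deduplicate undirected edges
    keys = u.astype(np.int64) * n + v
    _, first = np.unique(keys, return_index=True)
    edges = np.column_stack([u[first], v[first]]).astype(np.int64)
    weights = w[first]
    return Mesh(points=pts, n_sources=n_sources, edges=edges, weights=weights, p_m=p_m)


def mesh_cost(mesh: Mesh) -> float:
    """Total mesh length: sum of all unique edge weights (pixels)."""
    return float(mesh.weights.sum())
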