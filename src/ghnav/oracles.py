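"""Brute-force and closed-form references.

These are the ground truths the rest of the package is checked against:
exhaustive k-NN for recall, plain BFS for stretch denominators, the 1D
exact-Delaunay growth process (whose presence as a subgraph guarantees
greedy success), and the closed-form hop/stretch predictions of the
doubling argument: each doubling of the network adds a bounded number of
greedy hops, giving a 2·log2(N) hop bound, log2(N) shortest paths, and an
asymptotic stretch of 2.
"""

from __future__ import annotations

from bisect import bisect_left, insort
from collections import deque
from dataclasses import dataclass

import numpy as np

from .ghnet import GHNetwork
from .spaces import MetricDataset, PointDataset, PointSet, as_dataset

__all__ = [
    "TheoryBounds",
    "brute_force_knn",
    "bfs_shortest_path",
    "delaunay_1d_build",
    "theory_bounds",
]


@dataclass
class TheoryBounds:
    """Closed-form navigation predictions for a network of ``n`` elements."""

    n: int
    hop_upper_bound: float
    shortest_path_prediction: float
    stretch_prediction: float = 2.0


def theory_bounds(n: int) -> TheoryBounds:
    """2·log2(n) greedy-hop bound, log2(n) shortest paths, stretch 2."""
    if n < 2:
        raise ValueError("n must be >= 2")
    sp = float(np.log2(n))
    return TheoryBounds(n=n, hop_upper_bound=2.0 * sp, shortest_path_prediction=sp)


def brute_force_knn(dataset, query, K: int) -> np.ndarray:
    """Exact K nearest elements by exhaustive scan, ties to lower index.

    ``query`` is an element index or, for point data, a raw vector.
    Distances evaluated here are charged to the dataset counter like any
    other scan.
    """
    ds = as_dataset(dataset)
    n = len(ds)
    if not (1 <= K <= n):
        raise ValueError("K must satisfy 1 <= K <= dataset size")
    idx = np.arange(n, dtype=np.int64)
    if isinstance(query, (int, np.integer)):
        dist = ds.dists(idx, int(query))
    else:
        if not isinstance(ds, PointDataset):
            raise TypeError("vector queries require point data")
        dist = ds.dists_to_vector(idx, np.asarray(query, dtype=float))
    order = np.lexsort((idx, dist))
    return order[:K]


def bfs_shortest_path(network, a: int, b: int) -> int:
    """Minimal hop count between ``a`` and ``b`` (plain breadth-first search)."""
    adj = network.adjacency if isinstance(network, GHNetwork) else network
    if a == b:
        return 0
    seen = {a}
    frontier = deque([(a, 0)])
    while frontier:
        u, dist = frontier.popleft()
        for v in adj[u]:
            if v == b:
                return dist + 1
            if v not in seen:
                seen.add(v)
                frontier.append((v, dist + 1))
    raise ValueError(f"nodes {a} and {b} are disconnected")


def delaunay_1d_build(points: PointSet, extra_M: int = 0) -> GHNetwork:
    """Grow a network on 1D points connecting each insertion to its exact
    Delaunay neighbors among predecessors.

    In one dimension the Delaunay graph is the sorted linked list, so each
    new point links to its immediate left and right neighbors within the
    already-inserted prefix.  The final graph therefore contains the full
    sorted-order path as a subgraph, which makes greedy search exact (success
    ratio 1) for any query pair.  ``extra_M`` adds that many further
    nearest-predecessor links per insertion (0 keeps the pure Delaunay
    regime, which minimizes link overlap between generations).

    Points are inserted in the order given; permute beforehand for a random
    insertion order.
    """
    if points.d != 1:
        raise ValueError("delaunay_1d_build requires 1D points")
    coords = points.points[:, 0]
    if len(np.unique(coords)) != len(coords):
        raise ValueError("coordinates must be distinct")
    ds = PointDataset(points)
    n = len(ds)
    adj: list[list[int]] = [[] for _ in range(n)]
    # sorted list of (coordinate, node) over the inserted prefix
    inserted: list[tuple[float, int]] = [(float(coords[0]), 0)]
    for i in range(1, n):
        x = float(coords[i])
        pos = bisect_left(inserted, (x, i))
        nbrs = set()
        if pos > 0:
            nbrs.add(inserted[pos - 1][1])
        if pos < len(inserted):
            nbrs.add(inserted[pos][1])
        if extra_M > 0:
            dist = ds.dists(np.arange(i), i)
            for j in np.argsort(dist, kind="stable"):
                if len(nbrs) >= 2 + extra_M:
                    break
                nbrs.add(int(j))
        for j in nbrs:
            adj[j].append(i)
            adj[i].append(j)
        adj[i].sort()
        insort(inserted, (x, i))
    for lst in adj:
        lst.sort()
    return GHNetwork(
        dataset=ds,
        adjacency=adj,
        M=2 + extra_M,
        seed=points.seed,
        mode="exact",
        order=np.arange(n),
    )
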