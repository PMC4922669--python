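"""Growing-homophilic network construction.

A GH network is grown by inserting the elements of a metric dataset one at a
time in seeded random order.  Each new element links bidirectionally to its
``M`` nearest already-inserted elements — nearest either exactly (brute force
over the prefix) or approximately, by navigating the partially built graph
itself with a dynamic-candidate-list search whose trial count is calibrated
until measured recall clears a floor (0.95 by default).

The preferential-attachment (PA) variant replaces the plain metric by the
degree-normalized distance ``Δ / max(1, min(k, k_c))**(1/d)``: high-degree
nodes look closer, the bias saturating at degree ``k_c``.  With ``k_c = ∞``
this turns the exponential degree distribution of the base model into a power
law with exponent near 3; with finite ``k_c`` the power law is exponentially
truncated.

Node indices equal insertion ranks (node 0 was inserted first), so "element
age" is readable straight off the index — the earliest-inserted nodes form
the rich club.
"""

from __future__ import annotations

import math
import warnings
from bisect import insort
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import networkx as nx
from scipy import sparse

from .spaces import (
    MetricDataset,
    PointDataset,
    PointSet,
    StringSet,
    as_dataset,
)

__all__ = [
    "ConstructionConfig",
    "GHNetwork",
    "build",
    "build_exact",
    "build_approx",
    "build_pa",
    "knn_search",
    "measure_recall",
]


@dataclass
class ConstructionConfig:
    """Parameters of one GH construction run.

    M: links created per insertion (the model's single core parameter).
    mode: "exact" brute-forces each prefix; "approximate" navigates the
        partial graph (never touching all predecessors).
    n_trials: initial number of search restarts in approximate mode; the
        builder doubles it (cap ``trial_cap``) until probe recall reaches
        ``recall_floor``, recalibrating each time the network grows 10x.
    pa_enabled / k_c: preferential attachment via degree-normalized distance,
        saturated at degree ``k_c`` (``inf`` = pure power law).
    search_metric: metric the approximate insertion search navigates by:
        "auto" (plain for the base model, degree-normalized when PA is on),
        or forced "plain" / "degree_normalized".  Navigating by the
        normalized metric while still *selecting* plain-metric neighbors is
        what keeps insertion recall high on strongly clustered data, where a
        plain-metric search gets trapped inside the entry cluster.
    """

    M: int
    mode: str = "exact"
    n_trials: int = 1
    recall_floor: float = 0.95
    pa_enabled: bool = False
    k_c: float = math.inf
    seed: int = 0
    trial_cap: int = 64
    search_metric: str = "auto"
    shuffle: bool = True  # False inserts in dataset order (for controlled tests)

    def __post_init__(self) -> None:
        if self.M < 1:
            raise ValueError("M must be >= 1")
        if self.mode not in ("exact", "approximate"):
            raise ValueError("mode must be 'exact' or 'approximate'")
        if not (0.0 < self.recall_floor <= 1.0):
            raise ValueError("recall_floor must be in (0, 1]")
        if self.search_metric not in ("auto", "plain", "degree_normalized"):
            raise ValueError("search_metric must be auto, plain or degree_normalized")

    @property
    def search_pa(self) -> bool:
        """Whether the insertion search navigates by the normalized metric."""
        if self.search_metric == "auto":
            return self.pa_enabled
        return self.search_metric == "degree_normalized"


@dataclass
class GHNetwork:
    """Undirected graph over inserted elements; node index == insertion rank.

    ``dataset`` is the insertion-ordered view of the input data (element i is
    node i); ``order`` maps node index back to the caller's original element
    index.
    """

    dataset: MetricDataset
    adjacency: list
    M: int
    pa_enabled: bool = False
    k_c: float = math.inf
    seed: int = 0
    mode: str = "exact"
    order: np.ndarray | None = None
    build_distance_computations: int = 0
    _adj_arrays: tuple | None = field(default=None, repr=False, compare=False)
    _csr: sparse.csr_matrix | None = field(default=None, repr=False, compare=False)

    @property
    def n(self) -> int:
        return len(self.adjacency)

    def __len__(self) -> int:
        return self.n

    def neighbors(self, i: int) -> np.ndarray:
        """Neighbor indices of node ``i``, ascending (lowest rank first)."""
        if self._adj_arrays is None:
            self._adj_arrays = tuple(
                np.asarray(a, dtype=np.int64) for a in self.adjacency
            )
        return self._adj_arrays[i]

    @property
    def degrees(self) -> np.ndarray:
        return np.array([len(a) for a in self.adjacency], dtype=np.int64)

    @property
    def n_edges(self) -> int:
        return sum(len(a) for a in self.adjacency) // 2

    def edges(self) -> np.ndarray:
        """All undirected edges as an (E, 2) array with u < v."""
        out = [(u, v) for u in range(self.n) for v in self.adjacency[u] if u < v]
        return np.asarray(out, dtype=np.int64).reshape(-1, 2)

    def to_csr(self) -> sparse.csr_matrix:
        if self._csr is None:
            e = self.edges()
            data = np.ones(2 * len(e), dtype=np.int8)
            rows = np.concatenate([e[:, 0], e[:, 1]])
            cols = np.concatenate([e[:, 1], e[:, 0]])
            self._csr = sparse.csr_matrix((data, (rows, cols)), shape=(self.n, self.n))
        return self._csr

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n))
        g.add_edges_from(map(tuple, self.edges()))
        return g

    def node_labels(self, labels: Sequence) -> np.ndarray:
        """Map labels given in original dataset order onto node indices."""
        labels = np.asarray(labels)
        if self.order is None:
            return labels
        return labels[self.order]

    # -- serialization -----------------------------------------------------

    def write_edgelist(self, path: str | Path) -> None:
        """Two-column 0-based TSV with construction metadata in comments."""
        with Path(path).open("w") as fh:
            kc = "inf" if math.isinf(self.k_c) else repr(self.k_c)
            fh.write(
                f"# n={self.n}\tM={self.M}\tpa={int(self.pa_enabled)}"
                f"\tk_c={kc}\tseed={self.seed}\tmode={self.mode}\n"
            )
            for u, v in self.edges():
                fh.write(f"{u}\t{v}\n")

    @staticmethod
    def read_edgelist(path: str | Path) -> "tuple[np.ndarray, dict]":
        """Edge array plus the metadata dict from the comment header."""
        meta: dict[str, str] = {}
        edges = []
        for line in Path(path).read_text().splitlines():
            if line.startswith("#"):
                for tok in line[1:].strip().split("\t"):
                    k, _, v = tok.partition("=")
                    meta[k] = v
            elif line.strip():
                u, v = line.split("\t")
                edges.append((int(u), int(v)))
        return np.asarray(edges, dtype=np.int64).reshape(-1, 2), meta

    def write_graphml(self, path: str | Path) -> None:
        g = self.to_networkx()
        deg = self.degrees
        is_points = isinstance(self.dataset, PointDataset)
        for i in g.nodes:
            g.nodes[i]["insertion_rank"] = int(i)
            g.nodes[i]["degree"] = int(deg[i])
            if self.order is not None:
                g.nodes[i]["orig_index"] = int(self.order[i])
            if is_points:
                g.nodes[i]["coords"] = " ".join(
                    repr(float(x)) for x in self.dataset.points[i]
                )
        g.graph.update(
            M=self.M,
            pa=int(self.pa_enabled),
            k_c="inf" if math.isinf(self.k_c) else self.k_c,
            seed=self.seed,
            mode=self.mode,
        )
        nx.write_graphml(g, str(path))

    @classmethod
    def read_graphml(cls, path: str | Path, dataset=None) -> "GHNetwork":
        """Round-trip a written network.

        If ``dataset`` (the original PointSet/StringSet or a MetricDataset)
        is given it is re-permuted using the stored ``orig_index`` mapping;
        otherwise coordinates embedded in the file are used.
        """
        g = nx.read_graphml(str(path), node_type=int)
        n = g.number_of_nodes()
        adjacency: list[list[int]] = [sorted(map(int, g.neighbors(i))) for i in range(n)]
        meta = g.graph
        order = None
        if all("orig_index" in g.nodes[i] for i in range(n)):
            order = np.array([int(g.nodes[i]["orig_index"]) for i in range(n)])
        if dataset is not None:
            ds = as_dataset(dataset)
            if order is not None:
                ds = ds.permuted(order)
        else:
            coords = [g.nodes[i].get("coords") for i in range(n)]
            if any(c is None for c in coords):
                raise ValueError("graphml lacks coordinates; pass the dataset")
            pts = np.array([[float(x) for x in c.split()] for c in coords])
            ds = PointDataset(PointSet(points=pts, d=pts.shape[1]))
        kc_raw = meta.get("k_c", "inf")
        return cls(
            dataset=ds,
            adjacency=adjacency,
            M=int(meta.get("M", 0)),
            pa_enabled=bool(int(meta.get("pa", 0))),
            k_c=math.inf if kc_raw == "inf" else float(kc_raw),
            seed=int(meta.get("seed", 0)),
            mode=meta.get("mode", "exact"),
            order=order,
        )


# ---------------------------------------------------------------------------
# Selection keys
# ---------------------------------------------------------------------------


def _pa_divisor(deg: np.ndarray, k_c: float) -> np.ndarray:
    return np.maximum(1.0, np.minimum(deg, k_c))


def _select_smallest(key: np.ndarray, m: int) -> np.ndarray:
    """Indices of the ``m`` smallest keys, ties broken by lower index."""
    if m >= len(key):
        return np.argsort(key, kind="stable")
    part = np.argpartition(key, m - 1)[:m]
    return part[np.lexsort((part, key[part]))]


# ---------------------------------------------------------------------------
# Exact construction
# ---------------------------------------------------------------------------


def _build_core_exact(ds: MetricDataset, cfg: ConstructionConfig) -> list:
    n = len(ds)
    adj: list[list[int]] = [[] for _ in range(n)]
    deg = np.zeros(n, dtype=np.int64)
    pa = cfg.pa_enabled
    d = getattr(ds, "d", None)
    fast = isinstance(ds, PointDataset)
    idx_all = np.arange(n, dtype=np.int64)
    for i in range(1, n):
        if fast:
            key = ds.prefix_sqdists(i)  # squared: same ordering, fewer passes
            if pa:
                key = key / _pa_divisor(deg[:i], cfg.k_c) ** (2.0 / d)
        else:
            key = ds.dists(idx_all[:i], i)
            if pa:
                key = key / _pa_divisor(deg[:i], cfg.k_c) ** (1.0 / d)
        m = min(i, cfg.M)
        if i <= cfg.M:
            chosen = idx_all[:i]
        else:
            chosen = _select_smallest(key, m)
        # batch degree update: all M links of this insertion are chosen under
        # the pre-insertion degrees, then committed together
        lst = adj[i]
        for j in chosen:
            adj[int(j)].append(i)
            lst.append(int(j))
        lst.sort()
        deg[chosen] += 1
        deg[i] = m
    return adj


# ---------------------------------------------------------------------------
# Graph-navigated (approximate) k-NN search
# ---------------------------------------------------------------------------


def _graph_knn(
    ds: MetricDataset,
    adj: list,
    deg: np.ndarray,
    n_active: int,
    qdist: Callable[[np.ndarray], np.ndarray],
    K: int,
    n_trials: int,
    rng: np.random.Generator,
    pa: bool = False,
    k_c: float = math.inf,
    d: int | None = None,
    enter: int | None = None,
) -> dict:
    """Dynamic-list search over the first ``n_active`` nodes of the graph.

    Per trial: start from a random enter node, keep a list of the K closest
    elements discovered so far, repeatedly evaluate the neighborhood of the
    closest not-yet-evaluated list member, and stop once every list member
    has been evaluated.  For K=1 and one trial this is plain greedy search.
    Returns the union of all trials' final lists as a dict node -> key
    (callers rank it under their selection metric).
    """
    K = min(K, n_active)
    best: dict[int, float] = {}

    def keys_for(nodes: np.ndarray) -> np.ndarray:
        dist = qdist(nodes)
        if pa:
            return dist / _pa_divisor(deg[nodes], k_c) ** (1.0 / d)
        return dist

    for trial in range(n_trials):
        start = int(rng.integers(n_active)) if enter is None or trial > 0 else int(enter)
        seen = {start}
        w: list[tuple[float, int]] = [(float(keys_for(np.array([start]))[0]), start)]
        expanded: set[int] = set()
        while True:
            nxt = next(((k, v) for k, v in w if v not in expanded), None)
            if nxt is None:
                break
            expanded.add(nxt[1])
            fresh = [x for x in adj[nxt[1]] if x not in seen and x < n_active]
            if not fresh:
                continue
            seen.update(fresh)
            karr = keys_for(np.asarray(fresh, dtype=np.int64))
            for kx, node in zip(karr, fresh):
                entry = (float(kx), node)
                if len(w) < K or entry < w[-1]:
                    insort(w, entry)
                    if len(w) > K:
                        w.pop()
        for kx, node in w:
            if node not in best or kx < best[node]:
                best[node] = kx
    return best


def _pick_from_union(
    ds: MetricDataset,
    deg: np.ndarray,
    union: dict,
    query: int,
    M: int,
    select_pa: bool,
    search_pa: bool,
    k_c: float,
    d: int | None,
) -> list:
    """Rank a search union under the selection metric and keep the best M.

    When the search already navigated by the selection metric the stored
    keys are reused; otherwise the candidates are re-evaluated (counted)
    under the selection metric.
    """
    if select_pa == search_pa:
        ranked = sorted((k, v) for v, k in union.items())
        return [node for _, node in ranked[:M]]
    cand = np.fromiter(union.keys(), dtype=np.int64)
    dist = ds.dists(cand, query)
    key = dist / _pa_divisor(deg[cand], k_c) ** (1.0 / d) if select_pa else dist
    return [int(cand[j]) for j in _select_smallest(key, min(M, len(cand)))]


def _brute_truth(
    ds: MetricDataset,
    deg: np.ndarray,
    n_active: int,
    query: int,
    K: int,
    pa: bool,
    k_c: float,
    d: int | None,
) -> np.ndarray:
    idx = np.arange(n_active, dtype=np.int64)
    dist = ds.dists(idx, query)
    key = dist / _pa_divisor(deg[:n_active], k_c) ** (1.0 / d) if pa else dist
    return _select_smallest(key, min(K, n_active))


def _build_core_approx(ds: MetricDataset, cfg: ConstructionConfig) -> tuple[list, int]:
    n = len(ds)
    adj: list[list[int]] = [[] for _ in range(n)]
    deg = np.zeros(n, dtype=np.int64)
    pa = cfg.pa_enabled
    d = getattr(ds, "d", None)
    search_pa = cfg.search_pa
    if search_pa and d is None:
        raise ValueError("degree-normalized search requires vector data (needs d)")
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0xA99]))
    trials = max(1, cfg.n_trials)
    next_calib = max(100, 4 * cfg.M)

    for i in range(1, n):
        m = min(i, cfg.M)
        if i <= cfg.M:
            chosen: Sequence[int] = range(i)
        else:
            if i >= next_calib:
                trials = _calibrate_trials(ds, adj, deg, i, cfg, trials, rng)
                next_calib *= 10
            union = _graph_knn(
                ds, adj, deg, i, lambda nodes: ds.dists(nodes, i), cfg.M, trials,
                rng, pa=search_pa, k_c=cfg.k_c, d=d,
            )
            chosen = _pick_from_union(
                ds, deg, union, i, cfg.M, pa, search_pa, cfg.k_c, d
            )
        lst = adj[i]
        for j in chosen:
            adj[int(j)].append(i)
            lst.append(int(j))
        lst.sort()
        deg[list(chosen)] += 1
        deg[i] = m
    return adj, trials


def _calibrate_trials(
    ds, adj, deg, i, cfg: ConstructionConfig, trials: int, rng
) -> int:
    """Double the trial count until probe recall clears the floor (cap 64).

    Probes use up to 50 not-yet-inserted elements as queries against the
    current prefix, with brute force as ground truth.
    """
    n = len(ds)
    queries = list(range(i, min(i + 50, n)))
    if not queries:
        return trials
    pa, d = cfg.pa_enabled, getattr(ds, "d", None)
    search_pa = cfg.search_pa
    while True:
        recalls = []
        for q in queries:
            union = _graph_knn(
                ds, adj, deg, i, lambda nodes: ds.dists(nodes, q), cfg.M, trials,
                rng, pa=search_pa, k_c=cfg.k_c, d=d,
            )
            found = _pick_from_union(ds, deg, union, q, cfg.M, pa, search_pa, cfg.k_c, d)
            truth = _brute_truth(ds, deg, i, q, cfg.M, pa, cfg.k_c, d)
            recalls.append(measure_recall(found, truth))
        if float(np.mean(recalls)) >= cfg.recall_floor:
            return trials
        if trials >= cfg.trial_cap:
            warnings.warn(
                f"recall calibration hit the trial cap ({cfg.trial_cap}); "
                "construction proceeds with the cap",
                stacklevel=2,
            )
            return trials
        trials = min(2 * trials, cfg.trial_cap)


# ---------------------------------------------------------------------------
# Public builders
# ---------------------------------------------------------------------------


def build(dataset, config: ConstructionConfig) -> GHNetwork:
    """Build a GH network per ``config`` (dispatches on mode / PA flag)."""
    ds = as_dataset(dataset)
    if len(ds) < 2:
        raise ValueError("dataset must contain at least 2 elements")
    if config.pa_enabled and not isinstance(ds, PointDataset):
        raise ValueError("preferential attachment requires vector data (needs d)")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x6E]))
    perm = rng.permutation(len(ds)) if config.shuffle else np.arange(len(ds))
    permuted = ds.permuted(perm)
    c0 = permuted.counter.count
    if config.mode == "exact":
        adj = _build_core_exact(permuted, config)
    else:
        adj, _ = _build_core_approx(permuted, config)
    return GHNetwork(
        dataset=permuted,
        adjacency=adj,
        M=config.M,
        pa_enabled=config.pa_enabled,
        k_c=config.k_c,
        seed=config.seed,
        mode=config.mode,
        order=perm,
        build_distance_computations=permuted.counter.count - c0,
    )


def build_exact(dataset, config: ConstructionConfig) -> GHNetwork:
    """Exact construction: each insertion brute-forces its prefix."""
    if config.mode != "exact":
        raise ValueError("build_exact requires mode='exact'")
    return build(dataset, config)


def build_approx(dataset, config: ConstructionConfig) -> GHNetwork:
    """Approximate construction: insertions navigate the partial graph."""
    if config.mode != "approximate":
        raise ValueError("build_approx requires mode='approximate'")
    return build(dataset, config)


def build_pa(dataset, config: ConstructionConfig) -> GHNetwork:
    """Preferential-attachment construction (degree-normalized distance)."""
    if not config.pa_enabled:
        raise ValueError("build_pa requires pa_enabled=True")
    return build(dataset, config)


# ---------------------------------------------------------------------------
# Query-time search & recall
# ---------------------------------------------------------------------------


def knn_search(
    network: GHNetwork,
    query,
    K: int,
    n_trials: int = 1,
    seed: int = 0,
) -> np.ndarray:
    """Approximate K nearest nodes to ``query`` by navigating the network.

    ``query`` is either a node/element index of the network's dataset or,
    for point data, a raw coordinate vector.  Uses the network's own
    selection metric (degree-normalized when it was built with PA).
    Returns node indices sorted ascending by that metric.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    ds = network.dataset
    n = network.n
    if K > n:
        warnings.warn(f"K={K} exceeds network size {n}; returning all nodes")
        K = n
    if isinstance(query, (int, np.integer)):
        qdist = lambda nodes: ds.dists(nodes, int(query))  # noqa: E731
    else:
        if not isinstance(ds, PointDataset):
            raise TypeError("vector queries require point data")
        qvec = np.asarray(query, dtype=float)
        qdist = lambda nodes: ds.dists_to_vector(nodes, qvec)  # noqa: E731
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x5EEC]))
    deg = network.degrees
    union = _graph_knn(
        ds, network.adjacency, deg, n, qdist, K, n_trials, rng,
        pa=network.pa_enabled, k_c=network.k_c, d=getattr(ds, "d", None),
    )
    ranked = sorted((k, v) for v, k in union.items())
    return np.array([node for _, node in ranked[:K]], dtype=np.int64)


def measure_recall(found, truth) -> float:
    """|found ∩ truth| / |truth| — fraction of true neighbors recovered."""
    truth = list(truth)
    if not truth:
        raise ValueError("truth list must be non-empty")
    return len(set(map(int, found)) & set(map(int, truth))) / len(truth)
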