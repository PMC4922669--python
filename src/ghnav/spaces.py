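"""Synthetic metric datasets and counted distance evaluation.

The growing-homophilic (GH) construction and greedy routing see the data only
through a narrow contract: an ordered collection of elements plus a distance
oracle that counts every evaluation.  The counter is what makes "information
extraction locality" measurable — the algorithmic cost of a search is the
number of distance computations it performs, which is distinct from (and
bounded below by) its hop count.

Two concrete spaces are provided: points in the unit hypercube ``[0,1]^d``
under the Euclidean (L2) metric, and character strings under a jittered
Damerau–Levenshtein edit distance.  The jitter breaks the ties that an
integer-valued metric would otherwise produce at every greedy step; it is
derived by hashing the unordered string pair, so repeated evaluations of the
same pair agree and searches stay deterministic for a given seed.
"""

from __future__ import annotations

import contextlib
import hashlib
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np

__all__ = [
    "DistanceCounter",
    "PointSet",
    "StringSet",
    "MetricDataset",
    "PointDataset",
    "StringDataset",
    "as_dataset",
    "make_uniform_points",
    "make_clustered_points",
    "make_random_strings",
    "l2_distance",
    "damerau_levenshtein",
    "edit_distance_jittered",
    "degree_normalized_distance",
    "counting",
]


class DistanceCounter:
    """Monotone counter of distance evaluations.

    The count only ever increases during use; :meth:`reset` is the single
    explicit way to zero it.  Vectorized evaluations add the batch size, so
    the counter always equals the number of scalar distance computations an
    unvectorized implementation would have performed.
    """

    __slots__ = ("count",)

    def __init__(self) -> None:
        self.count: int = 0

    def add(self, n: int = 1) -> None:
        self.count += int(n)

    def reset(self) -> None:
        self.count = 0

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"DistanceCounter(count={self.count})"


# Module-level "active" counter used by the standalone distance functions.
_ACTIVE_COUNTER: DistanceCounter | None = None


@contextlib.contextmanager
def counting(counter: DistanceCounter) -> Iterator[DistanceCounter]:
    """Make ``counter`` the active counter for standalone distance calls."""
    global _ACTIVE_COUNTER
    prev = _ACTIVE_COUNTER
    _ACTIVE_COUNTER = counter
    try:
        yield counter
    finally:
        _ACTIVE_COUNTER = prev


def _tick(n: int = 1) -> None:
    if _ACTIVE_COUNTER is not None:
        _ACTIVE_COUNTER.add(n)


# ---------------------------------------------------------------------------
# Element collections
# ---------------------------------------------------------------------------


@dataclass
class PointSet:
    """Points in the unit hypercube ``[0,1]^d``.

    ``labels`` records a cluster assignment per point when the set was drawn
    from a clustered generator, else ``None``.
    """

    points: np.ndarray
    d: int
    labels: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != self.d:
            raise ValueError(f"points must be (n, {self.d}) shaped")
        if np.any(self.points < 0.0) or np.any(self.points > 1.0):
            raise ValueError("coordinates must lie in [0, 1]")
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if len(self.labels) != len(self.points):
                raise ValueError("labels must have one entry per point")

    def __len__(self) -> int:
        return len(self.points)

    def to_tsv(self, path: str | Path) -> None:
        path = Path(path)
        with path.open("w") as fh:
            fh.write(f"# d={self.d}\n# seed={self.seed}\n")
            if self.labels is not None:
                fh.write("# labels=1\n")
            for i, p in enumerate(self.points):
                row = "\t".join(repr(float(x)) for x in p)
                if self.labels is not None:
                    row += f"\t{self.labels[i]}"
                fh.write(row + "\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PointSet":
        meta: dict[str, str] = {}
        rows: list[list[str]] = []
        for line in Path(path).read_text().splitlines():
            if line.startswith("#"):
                key, _, val = line[1:].strip().partition("=")
                meta[key.strip()] = val.strip()
            elif line.strip():
                rows.append(line.split("\t"))
        d = int(meta["d"])
        has_labels = meta.get("labels") == "1"
        pts = np.array([[float(x) for x in r[:d]] for r in rows])
        labels = np.array([int(r[d]) for r in rows]) if has_labels else None
        return cls(points=pts, d=d, labels=labels, seed=int(meta.get("seed", 0)))


@dataclass
class StringSet:
    """A collection of non-empty strings over a fixed alphabet."""

    strings: list[str]
    alphabet: str
    seed: int = 0

    def __post_init__(self) -> None:
        alpha = set(self.alphabet)
        for s in self.strings:
            if not s:
                raise ValueError("strings must be non-empty")
            if not set(s) <= alpha:
                raise ValueError(f"string {s!r} uses characters outside the alphabet")

    def __len__(self) -> int:
        return len(self.strings)

    def to_tsv(self, path: str | Path) -> None:
        path = Path(path)
        with path.open("w") as fh:
            fh.write(f"# alphabet={self.alphabet}\n# seed={self.seed}\n")
            for s in self.strings:
                fh.write(s + "\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "StringSet":
        meta: dict[str, str] = {}
        strings: list[str] = []
        for line in Path(path).read_text().splitlines():
            if line.startswith("#"):
                key, _, val = line[1:].strip().partition("=")
                meta[key.strip()] = val.strip()
            elif line.strip():
                strings.append(line.strip())
        return cls(strings=strings, alphabet=meta["alphabet"], seed=int(meta.get("seed", 0)))


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------


def make_uniform_points(n: int, d: int, seed: int = 0) -> PointSet:
    """``n`` i.i.d. uniform points in ``[0,1]^d``.

    Identical seeds give bitwise-identical point sets.
    """
    if n < 1 or d < 1:
        raise ValueError("n and d must be positive")
    rng = np.random.default_rng(seed)
    return PointSet(points=rng.random((n, d)), d=d, seed=seed)


def make_clustered_points(
    n: int, d: int, n_clusters: int, spread: float = 0.01, seed: int = 0
) -> PointSet:
    """Gaussian clusters around uniform centers, confined to the unit cube.

    Cluster sizes are as equal as possible; each member is scattered
    isotropically around its center with scale ``spread``, resampling draws
    that fall outside the cube (clipping only as a last resort, which keeps
    the in-cube invariant unconditional).
    """
    if n < 1 or d < 1 or n_clusters < 1:
        raise ValueError("n, d and n_clusters must be positive")
    if n_clusters > n:
        raise ValueError("n_clusters may not exceed n")
    rng = np.random.default_rng(seed)
    centers = rng.random((n_clusters, d))
    # round-robin assignment gives |size_i - size_j| <= 1
    labels = np.arange(n) % n_clusters
    rng.shuffle(labels)
    pts = np.empty((n, d))
    for i, lab in enumerate(labels):
        c = centers[lab]
        for _ in range(100):
            p = c + rng.normal(scale=spread, size=d)
            if np.all((p >= 0.0) & (p <= 1.0)):
                break
        else:
            p = np.clip(p, 0.0, 1.0)
        pts[i] = p
    return PointSet(points=pts, d=d, labels=labels, seed=seed)


def make_random_strings(
    n: int, alphabet: str, min_len: int, max_len: int, seed: int = 0
) -> StringSet:
    """Random strings with lengths uniform on ``[min_len, max_len]``."""
    if n < 1:
        raise ValueError("n must be positive")
    if not alphabet:
        raise ValueError("alphabet must be non-empty")
    if not (1 <= min_len <= max_len):
        raise ValueError("need 1 <= min_len <= max_len")
    rng = np.random.default_rng(seed)
    chars = list(alphabet)
    lengths = rng.integers(min_len, max_len + 1, size=n)
    strings = [
        "".join(chars[j] for j in rng.integers(0, len(chars), size=L)) for L in lengths
    ]
    return StringSet(strings=strings, alphabet=alphabet, seed=seed)


# ---------------------------------------------------------------------------
# Distance functions
# ---------------------------------------------------------------------------


def l2_distance(a: Sequence[float], b: Sequence[float]) -> float:
    """Euclidean distance; increments the active :class:`DistanceCounter` by 1."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("dimension mismatch")
    _tick()
    return float(np.linalg.norm(a - b))


def damerau_levenshtein(a: str, b: str) -> int:
    """Restricted Damerau–Levenshtein distance (adjacent transpositions).

    Dynamic programming over three rolling rows; insertions, deletions,
    substitutions and adjacent transpositions each cost 1.
    """
    la, lb = len(a), len(b)
    if la == 0:
        return lb
    if lb == 0:
        return la
    prev2 = [0] * (lb + 1)
    prev = list(range(lb + 1))
    for i in range(1, la + 1):
        cur = [i] + [0] * lb
        ai = a[i - 1]
        for j in range(1, lb + 1):
            cost = 0 if ai == b[j - 1] else 1
            cur[j] = min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + cost)
            if i > 1 and j > 1 and ai == b[j - 2] and a[i - 2] == b[j - 1]:
                cur[j] = min(cur[j], prev2[j - 2] + 1)
        prev2, prev = prev, cur
    return prev[lb]


def _pair_jitter(a: str, b: str, scale: float) -> float:
    """Deterministic pseudo-random jitter in ``[0, scale)`` for an unordered pair."""
    lo, hi = (a, b) if a <= b else (b, a)
    digest = hashlib.blake2b(
        lo.encode("utf-8") + b"\x1f" + hi.encode("utf-8"), digest_size=8
    ).digest()
    return int.from_bytes(digest, "big") / 2**64 * scale


def edit_distance_jittered(a: str, b: str, jitter_scale: float = 0.1) -> float:
    """Damerau–Levenshtein distance plus a symmetric, reproducible jitter.

    The jitter lies in ``[0, jitter_scale)`` and is a hash of the unordered
    pair, so ``d(a, b) == d(b, a)`` exactly and repeated evaluations agree —
    greedy routing can "unambiguously select the next node" without the
    integer ties a plain edit distance would produce.  With
    ``jitter_scale < 0.5`` the ordering of distinct base distances is
    preserved.  Increments the active counter by 1.
    """
    if not (0.0 <= jitter_scale < 0.5):
        raise ValueError("jitter_scale must be in [0, 0.5)")
    _tick()
    return damerau_levenshtein(a, b) + _pair_jitter(a, b, jitter_scale)


def degree_normalized_distance(delta, k, d: int, k_c: float = math.inf):
    """Metric distance discounted by node degree: ``delta / max(1, min(k, k_c))**(1/d)``.

    This is the preferential-attachment ingredient: dividing by a power of
    the candidate's degree makes high-degree nodes effectively closer, with
    the preference saturating at degree ``k_c``.  The exponent ``1/d`` ties
    the bias to the dimensionality of the underlying vector space.  Degree 0
    (an isolated node, possible only transiently) is clamped to 1.  Accepts
    scalars or arrays.
    """
    if d < 1 or k_c < 1:
        raise ValueError("d and k_c must be >= 1")
    delta_arr = np.asarray(delta, dtype=float)
    if np.any(delta_arr < 0):
        raise ValueError("delta must be non-negative")
    eff = np.maximum(1.0, np.minimum(np.asarray(k, dtype=float), k_c))
    out = delta_arr / eff ** (1.0 / d)
    if np.isscalar(delta) or delta_arr.ndim == 0:
        return float(out)
    return out


# ---------------------------------------------------------------------------
# Counted datasets
# ---------------------------------------------------------------------------


class MetricDataset:
    """Ordered element collection plus a counting distance oracle.

    Subclasses implement :meth:`_dist` (scalar) and may override
    :meth:`dists` with a vectorized path.  All public distance entry points
    charge the counter with exactly one unit per element pair evaluated.
    """

    counter: DistanceCounter

    def __len__(self) -> int:  # pragma: no cover - abstract
        raise NotImplementedError

    def _dist(self, i: int, j: int) -> float:  # pragma: no cover - abstract
        raise NotImplementedError

    def distance(self, i: int, j: int) -> float:
        """Counted distance between elements ``i`` and ``j``."""
        self.counter.add(1)
        return self._dist(i, j)

    def raw_distance(self, i: int, j: int) -> float:
        """Uncounted distance, for bookkeeping outside a search (e.g. the
        searcher's own distance to the target, which it is assumed to know)."""
        return self._dist(i, j)

    def dists(self, indices: np.ndarray, j: int) -> np.ndarray:
        """Counted distances from each element of ``indices`` to element ``j``."""
        indices = np.asarray(indices, dtype=np.int64)
        self.counter.add(len(indices))
        return np.array([self._dist(int(i), j) for i in indices])

    def permuted(self, order: np.ndarray) -> "MetricDataset":  # pragma: no cover
        raise NotImplementedError


class PointDataset(MetricDataset):
    """L2 metric over a :class:`PointSet`, with vectorized counted batches."""

    def __init__(self, pointset: PointSet, counter: DistanceCounter | None = None):
        self.pointset = pointset
        self.points = np.ascontiguousarray(pointset.points)
        self.d = pointset.d
        self.counter = counter if counter is not None else DistanceCounter()
        self._sqnorms = np.einsum("ij,ij->i", self.points, self.points)

    def __len__(self) -> int:
        return len(self.points)

    def _dist(self, i: int, j: int) -> float:
        return float(np.linalg.norm(self.points[i] - self.points[j]))

    def dists(self, indices: np.ndarray, j: int) -> np.ndarray:
        indices = np.asarray(indices, dtype=np.int64)
        self.counter.add(len(indices))
        diff = self.points[indices] - self.points[j]
        return np.sqrt(np.einsum("ij,ij->i", diff, diff))

    def dists_to_vector(self, indices: np.ndarray, q: np.ndarray) -> np.ndarray:
        """Counted distances from dataset elements to an external query vector."""
        indices = np.asarray(indices, dtype=np.int64)
        q = np.asarray(q, dtype=float)
        if q.shape != (self.d,):
            raise ValueError("query dimension mismatch")
        self.counter.add(len(indices))
        diff = self.points[indices] - q
        return np.sqrt(np.einsum("ij,ij->i", diff, diff))

    def prefix_sqdists(self, i: int) -> np.ndarray:
        """Counted *squared* distances from elements ``0..i-1`` to element ``i``.

        Uses the ``|p|^2 - 2 p·q + |q|^2`` expansion so exact construction
        over a growing prefix stays a BLAS matrix-vector product.  Squared
        distances preserve every ordering the builders need; the counter is
        charged one unit per pair, the same as for true distances.
        """
        self.counter.add(i)
        q = self.points[i]
        out = self._sqnorms[:i] - 2.0 * (self.points[:i] @ q) + self._sqnorms[i]
        np.maximum(out, 0.0, out=out)
        return out

    def permuted(self, order: np.ndarray) -> "PointDataset":
        ps = PointSet(
            points=self.points[order],
            d=self.d,
            labels=None if self.pointset.labels is None else self.pointset.labels[order],
            seed=self.pointset.seed,
        )
        return PointDataset(ps, counter=self.counter)


class StringDataset(MetricDataset):
    """Jittered Damerau–Levenshtein metric over a :class:`StringSet`."""

    def __init__(
        self,
        stringset: StringSet,
        jitter_scale: float = 0.1,
        counter: DistanceCounter | None = None,
    ):
        self.stringset = stringset
        self.strings = list(stringset.strings)
        self.jitter_scale = jitter_scale
        self.counter = counter if counter is not None else DistanceCounter()

    def __len__(self) -> int:
        return len(self.strings)

    def _dist(self, i: int, j: int) -> float:
        return damerau_levenshtein(self.strings[i], self.strings[j]) + _pair_jitter(
            self.strings[i], self.strings[j], self.jitter_scale
        )

    def permuted(self, order: np.ndarray) -> "StringDataset":
        ss = StringSet(
            strings=[self.strings[int(i)] for i in order],
            alphabet=self.stringset.alphabet,
            seed=self.stringset.seed,
        )
        return StringDataset(ss, jitter_scale=self.jitter_scale, counter=self.counter)


def as_dataset(obj, **kwargs) -> MetricDataset:
    """Wrap a :class:`PointSet` or :class:`StringSet` in its counted dataset."""
    if isinstance(obj, MetricDataset):
        return obj
    if isinstance(obj, PointSet):
        return PointDataset(obj, **kwargs)
    if isinstance(obj, StringSet):
        return StringDataset(obj, **kwargs)
    raise TypeError(f"cannot build a MetricDataset from {type(obj).__name__}")
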