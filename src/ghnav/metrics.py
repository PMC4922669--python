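"""Quantitative analyses of GH-network navigability.

Covers routing statistics over seeded pair samples, scaling experiments
across size ladders (hops linear in log N for the base model; distance
computations power-law for pure preferential attachment), tail fits of the
degree distribution (exponential vs discrete power law with KS-selected
k_min), the link-length exponent alpha = d + 1, rich-club structure and its
size-independent navigability, clustering self-similarity, intermodular link
accounting for clustered data, stretch against BFS shortest paths, and the
analytic 2·log2(N) hop bound.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import networkx as nx
from scipy import optimize, sparse, special, stats

from .ghnet import GHNetwork
from .navigate import SearchResult, greedy_search, modified_greedy_search
from .spaces import PointDataset

__all__ = [
    "UndefinedFitError",
    "NavigationStats",
    "ScalingResult",
    "TailFit",
    "LinkLengthFit",
    "RichClubCurve",
    "RichClubNavResult",
    "IntermodularLinks",
    "StretchResult",
    "sample_pairs",
    "navigation_stats",
    "scaling_experiment",
    "degree_tail_fit",
    "link_length_exponent",
    "rich_club_connection_curve",
    "rich_club_navigability_test",
    "clustering_self_similarity",
    "count_intermodular_links",
    "stretch",
    "hop_upper_bound_check",
]


class UndefinedFitError(ValueError):
    """Raised when a distribution fit is requested on degenerate data."""


# ---------------------------------------------------------------------------
# Pair sampling and routing statistics
# ---------------------------------------------------------------------------


def sample_pairs(
    network: GHNetwork,
    n_pairs: int,
    seed: int = 0,
    restrict_to_first: int | None = None,
) -> np.ndarray:
    """Seeded uniform (start, target) pairs with start != target.

    With ``restrict_to_first=m`` both endpoints are drawn from insertion
    ranks < m — the protocol for probing rich-club navigability, since the
    earliest-inserted nodes are the rich club.  Sampling is with replacement
    across pairs.
    """
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    m = network.n if restrict_to_first is None else int(restrict_to_first)
    if not (2 <= m <= network.n):
        raise ValueError("need at least 2 eligible nodes")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x9A12]))
    starts = rng.integers(0, m, size=n_pairs)
    targets = rng.integers(0, m, size=n_pairs)
    clash = starts == targets
    while np.any(clash):
        targets[clash] = rng.integers(0, m, size=int(clash.sum()))
        clash = starts == targets
    return np.column_stack([starts, targets])


@dataclass
class NavigationStats:
    success_ratio: float
    mean_hops: float  # over successful searches only
    mean_distance_computations: float  # over all searches
    n_pairs: int


def _run_search(network, s, t, algorithm: str, k_c=None) -> SearchResult:
    if algorithm == "plain":
        return greedy_search(network, int(s), int(t))
    if algorithm == "modified":
        return modified_greedy_search(network, int(s), int(t), k_c=k_c)
    raise ValueError("algorithm must be 'plain' or 'modified'")


def navigation_stats(
    network: GHNetwork,
    pairs: np.ndarray,
    algorithm: str = "plain",
    k_c: float | None = None,
) -> NavigationStats:
    """Aggregate greedy-search outcomes over a pair sample.

    The success ratio counts searches whose terminal node is the target.
    Mean hops averages successful searches only (failures are reported via
    the success ratio); mean distance computations — the information
    extraction locality — averages all searches.
    """
    pairs = np.asarray(pairs)
    if len(pairs) == 0:
        raise ValueError("pairs must be non-empty")
    succ = 0
    hop_sum = 0
    comp_sum = 0
    for s, t in pairs:
        r = _run_search(network, s, t, algorithm, k_c)
        comp_sum += r.distance_computations
        if r.success:
            succ += 1
            hop_sum += r.hops
    return NavigationStats(
        success_ratio=succ / len(pairs),
        mean_hops=hop_sum / succ if succ else math.nan,
        mean_distance_computations=comp_sum / len(pairs),
        n_pairs=len(pairs),
    )


# ---------------------------------------------------------------------------
# Scaling experiments
# ---------------------------------------------------------------------------


@dataclass
class ScalingResult:
    """Per-size summary plus the better-fitting scaling law.

    ``model`` is "linear-in-logN" (quantity ~ a + b·log2 N) or "power-law"
    (log quantity ~ a + b·log N), chosen by R² on the respective transformed
    axes with identical point counts; exact ties are reported as "tie".
    ``fits`` keeps both candidate fits as (slope, intercept, r_squared).
    """

    sizes: list
    means: list
    errs: list
    model: str
    slope: float
    r_squared: float
    fits: dict = field(default_factory=dict)


def _fit_scaling(sizes, means) -> tuple[str, float, float, dict]:
    sizes = np.asarray(sizes, dtype=float)
    means = np.asarray(means, dtype=float)
    lin = stats.linregress(np.log2(sizes), means)
    plaw = stats.linregress(np.log(sizes), np.log(means))
    fits = {
        "linear-in-logN": (lin.slope, lin.intercept, lin.rvalue**2),
        "power-law": (plaw.slope, plaw.intercept, plaw.rvalue**2),
    }
    r_lin, r_pl = lin.rvalue**2, plaw.rvalue**2
    if r_lin == r_pl:
        return "tie", lin.slope, r_lin, fits
    if r_lin > r_pl:
        return "linear-in-logN", lin.slope, r_lin, fits
    return "power-law", plaw.slope, r_pl, fits


def scaling_experiment(
    builder,
    sizes,
    quantity: str = "hops",
    seeds=(0,),
    n_pairs: int = 1000,
    algorithm: str = "plain",
) -> ScalingResult:
    """Measure mean hops or distance computations across a size ladder.

    ``builder`` is a callable ``(n, seed) -> GHNetwork``.  For each size the
    quantity is averaged over ``n_pairs`` seeded pairs and over seeds; both
    a linear-in-log2(N) and a log-log model are fitted to the per-size means
    and the better one (by R²) is reported.
    """
    sizes = sorted(int(s) for s in sizes)
    if len(sizes) < 2:
        raise ValueError("need at least 2 sizes")
    if quantity not in ("hops", "computations"):
        raise ValueError("quantity must be 'hops' or 'computations'")
    means, errs = [], []
    for n in sizes:
        vals = []
        for seed in seeds:
            net = builder(n, seed)
            pairs = sample_pairs(net, n_pairs, seed=seed + 1)
            st = navigation_stats(net, pairs, algorithm=algorithm)
            vals.append(
                st.mean_hops if quantity == "hops" else st.mean_distance_computations
            )
        vals = np.asarray(vals, dtype=float)
        means.append(float(np.mean(vals)))
        errs.append(float(np.std(vals, ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else 0.0)
    model, slope, r2, fits = _fit_scaling(sizes, means)
    return ScalingResult(
        sizes=sizes, means=means, errs=errs, model=model, slope=slope,
        r_squared=r2, fits=fits,
    )


# ---------------------------------------------------------------------------
# Degree-tail fitting
# ---------------------------------------------------------------------------


@dataclass
class TailFit:
    family: str  # "exponential" | "power_law"
    exponent: float  # gamma for power law, rate for exponential
    k_min: int
    goodness: float  # KS distance between empirical and fitted tail CDF
    cutoff: float | None = None
    method: str = ""


def _discrete_powerlaw_mle(tail: np.ndarray, k_min: int) -> float:
    """Exact discrete power-law MLE: maximize -n log zeta(g, k_min) - g sum log k."""
    log_sum = float(np.sum(np.log(tail)))
    n = len(tail)

    def nll(g):
        return n * math.log(special.zeta(g, k_min)) + g * log_sum

    res = optimize.minimize_scalar(nll, bounds=(1.01, 8.0), method="bounded")
    return float(res.x)


def _powerlaw_ks(tail: np.ndarray, k_min: int, gamma: float) -> float:
    kmax = int(tail.max())
    ks_range = np.arange(k_min, kmax + 1)
    pmf = ks_range ** (-gamma) / special.zeta(gamma, k_min)
    cdf = np.cumsum(pmf)
    emp = np.searchsorted(np.sort(tail), ks_range, side="right") / len(tail)
    return float(np.max(np.abs(emp - cdf)))


def _geometric_ks(excess: np.ndarray, p: float) -> float:
    kmax = int(excess.max())
    ks_range = np.arange(0, kmax + 1)
    cdf = 1.0 - (1.0 - p) ** (ks_range + 1)
    emp = np.searchsorted(np.sort(excess), ks_range, side="right") / len(excess)
    return float(np.max(np.abs(emp - cdf)))


def degree_tail_fit(
    network_or_degrees,
    family: str = "exponential",
    k_min: int | None = None,
    min_tail: int = 100,
    max_kmin_candidates: int = 50,
) -> TailFit:
    """Fit the degree-distribution tail.

    exponential: discrete geometric (exponential-tail) MLE on the excess
    over ``k_min`` (default 2M for a network, else the minimum degree); the
    reported exponent is the decay rate λ in survival ~ exp(−λ k).

    power_law: exact discrete maximum likelihood for P(k) ∝ k^(−γ), with
    ``k_min`` selected by minimizing the Kolmogorov–Smirnov distance between
    the empirical tail and the fitted zeta tail (candidates capped at
    ``max_kmin_candidates`` values whose tails keep ≥ ``min_tail`` points).
    Pass ``k_min`` explicitly to skip the selection.
    """
    if isinstance(network_or_degrees, GHNetwork):
        degrees = network_or_degrees.degrees
        default_kmin = 2 * network_or_degrees.M
    else:
        degrees = np.asarray(network_or_degrees, dtype=np.int64)
        default_kmin = int(degrees.min()) if len(degrees) else 1
    degrees = degrees[degrees >= 1]
    if len(degrees) < 10:
        raise UndefinedFitError("too few positive degrees to fit a tail")
    if np.all(degrees == degrees[0]):
        raise UndefinedFitError("constant degree sequence has no tail to fit")

    if family == "exponential":
        km = int(k_min) if k_min is not None else default_kmin
        tail = degrees[degrees >= km]
        if len(tail) < 10 or np.all(tail == tail[0]):
            raise UndefinedFitError(f"degenerate tail above k_min={km}")
        excess = tail - km
        mean_excess = float(np.mean(excess))
        p = 1.0 / (1.0 + mean_excess)  # geometric MLE on the excess
        rate = -math.log1p(-p)
        return TailFit(
            family="exponential", exponent=rate, k_min=km,
            goodness=_geometric_ks(excess, p), method="geometric MLE + KS",
        )

    if family == "power_law":
        if k_min is not None:
            candidates = [int(k_min)]
        else:
            uniq = np.unique(degrees)
            uniq = uniq[
                np.searchsorted(np.sort(degrees), uniq, side="left")
                <= len(degrees) - min_tail
            ]
            if len(uniq) == 0:
                uniq = np.unique(degrees)[:1]
            if len(uniq) > max_kmin_candidates:
                pick = np.linspace(0, len(uniq) - 1, max_kmin_candidates).astype(int)
                uniq = uniq[np.unique(pick)]
            candidates = [int(k) for k in uniq]
        best: TailFit | None = None
        for km in candidates:
            tail = degrees[degrees >= km]
            if len(tail) < 10 or np.all(tail == tail[0]):
                continue
            gamma = _discrete_powerlaw_mle(tail, km)
            ks = _powerlaw_ks(tail, km, gamma)
            if best is None or ks < best.goodness:
                best = TailFit(
                    family="power_law", exponent=gamma, k_min=km, goodness=ks,
                    method="discrete MLE + KS-selected k_min",
                )
        if best is None:
            raise UndefinedFitError("no viable k_min candidate")
        return best

    raise ValueError("family must be 'exponential' or 'power_law'")


# ---------------------------------------------------------------------------
# Link lengths
# ---------------------------------------------------------------------------


@dataclass
class LinkLengthFit:
    alpha: float
    fit_range: tuple
    n_bins_used: int
    r_squared: float


def link_length_exponent(
    network: GHNetwork, n_bins: int = 40, upper_quantile: float = 0.999
) -> LinkLengthFit:
    """Tail exponent of the edge-length density, predicted alpha = d + 1.

    Edge lengths are log-binned and the density fitted by least squares on
    log-log axes over a central window.  Lengths below the final M-th
    nearest-neighbor scale ``(M/n)**(1/d)`` are excluded — links shorter
    than that are still being laid down when growth stops, so their density
    has not yet reached the stationary power law — and so are the top
    ``1 - upper_quantile`` of lengths, where the cube boundary truncates
    the density.
    """
    ds = network.dataset
    if not isinstance(ds, PointDataset):
        raise ValueError("link lengths require point data")
    e = network.edges()
    if len(e) == 0:
        raise UndefinedFitError("network has no edges")
    diff = ds.points[e[:, 0]] - ds.points[e[:, 1]]
    lengths = np.sqrt(np.einsum("ij,ij->i", diff, diff))
    if np.ptp(lengths) == 0:
        raise UndefinedFitError("all link lengths equal; density is degenerate")
    r_lo = (max(network.M, 1) / network.n) ** (1.0 / ds.d)
    r_hi = float(np.quantile(lengths, upper_quantile))
    if not (r_hi > r_lo):
        raise UndefinedFitError("fit window is empty")
    bins = np.logspace(np.log10(lengths.min() * 0.999), np.log10(lengths.max() * 1.001), n_bins + 1)
    counts, edges = np.histogram(lengths, bins=bins)
    widths = np.diff(edges)
    centers = np.sqrt(edges[:-1] * edges[1:])
    density = counts / widths
    keep = (counts > 5) & (centers >= r_lo) & (centers <= r_hi)
    if keep.sum() < 3:
        raise UndefinedFitError("too few bins in the fit window")
    fit = stats.linregress(np.log(centers[keep]), np.log(density[keep]))
    return LinkLengthFit(
        alpha=float(-fit.slope),
        fit_range=(r_lo, r_hi),
        n_bins_used=int(keep.sum()),
        r_squared=float(fit.rvalue**2),
    )


# ---------------------------------------------------------------------------
# Rich club
# ---------------------------------------------------------------------------


@dataclass
class RichClubCurve:
    bin_edges: np.ndarray  # degree-bin edges, length n_bins + 1
    probability: np.ndarray  # P(connected | min endpoint degree in bin)
    n_pairs: np.ndarray
    n_edges: np.ndarray


def rich_club_connection_curve(network: GHNetwork, n_bins: int = 8) -> RichClubCurve:
    """Connection probability of node pairs binned by their smaller degree.

    Computed exactly: for each log-spaced degree bin the number of node
    pairs whose minimum degree falls in the bin follows from the degree
    histogram, and the connected pairs are counted from the edge list.  In
    GH networks this probability grows steeply (exponentially) with degree —
    the rich-club signature.
    """
    deg = network.degrees
    dmin, dmax = int(deg.min()), int(deg.max())
    if dmin == dmax:
        edges_bins = np.array([dmin, dmax + 1], dtype=float)
    else:
        edges_bins = np.unique(
            np.round(np.logspace(np.log10(max(dmin, 1)), np.log10(dmax + 1), n_bins + 1))
        ).astype(float)
    nb = len(edges_bins) - 1
    which = np.clip(np.digitize(deg, edges_bins) - 1, 0, nb - 1)
    counts = np.bincount(which, minlength=nb)
    higher = np.concatenate([np.cumsum(counts[::-1])[::-1][1:], [0]])
    pairs = counts * (counts - 1) // 2 + counts * higher
    e = network.edges()
    if len(e):
        emin = np.minimum(which[e[:, 0]], which[e[:, 1]])
        edge_counts = np.bincount(emin, minlength=nb)
    else:
        edge_counts = np.zeros(nb, dtype=np.int64)
    with np.errstate(invalid="ignore", divide="ignore"):
        prob = np.where(pairs > 0, edge_counts / np.maximum(pairs, 1), 0.0)
    return RichClubCurve(
        bin_edges=edges_bins, probability=prob, n_pairs=pairs, n_edges=edge_counts
    )


@dataclass
class RichClubNavResult:
    sizes: list
    hops_restricted: list  # pairs drawn from the first n_first nodes
    hops_all: list
    slope_restricted: float  # vs log2 n
    slope_all: float


def rich_club_navigability_test(
    builder,
    n_first: int,
    sizes,
    seeds=(0,),
    n_pairs: int = 1000,
) -> RichClubNavResult:
    """Mean greedy hops for early-rank pairs vs all pairs across a ladder.

    The rich club (first ``n_first`` insertions) is itself navigable: routes
    between early nodes ignore later additions, so the restricted curve is
    flat in network size while the unrestricted curve keeps its logarithmic
    growth.
    """
    sizes = sorted(int(s) for s in sizes)
    if n_first > sizes[0]:
        raise ValueError("n_first must not exceed the smallest ladder size")
    hr, ha = [], []
    for n in sizes:
        vr, va = [], []
        for seed in seeds:
            net = builder(n, seed)
            pr = sample_pairs(net, n_pairs, seed=seed + 1, restrict_to_first=n_first)
            pa = sample_pairs(net, n_pairs, seed=seed + 1)
            vr.append(navigation_stats(net, pr).mean_hops)
            va.append(navigation_stats(net, pa).mean_hops)
        hr.append(float(np.mean(vr)))
        ha.append(float(np.mean(va)))
    x = np.log2(np.asarray(sizes, dtype=float))
    slope_r = float(stats.linregress(x, hr).slope) if len(sizes) > 1 else 0.0
    slope_a = float(stats.linregress(x, ha).slope) if len(sizes) > 1 else 0.0
    return RichClubNavResult(
        sizes=sizes, hops_restricted=hr, hops_all=ha,
        slope_restricted=slope_r, slope_all=slope_a,
    )


# ---------------------------------------------------------------------------
# Self-similarity and modularity
# ---------------------------------------------------------------------------


def clustering_self_similarity(
    network: GHNetwork,
    ball_radii,
    n_centers: int = 20,
    seed: int = 0,
) -> np.ndarray:
    """Mean local clustering coefficient of metric-ball-induced subgraphs.

    For each radius, ``n_centers`` ball centers are sampled uniformly from
    the point set and the average clustering coefficient of each induced
    subgraph is averaged over centers.  A radius-independent profile is the
    self-similarity readout: any ball cut out of a uniform-data GH network
    looks statistically like a smaller GH network.  Balls with fewer than 3
    nodes are skipped with a warning.
    """
    ds = network.dataset
    if not isinstance(ds, PointDataset):
        raise ValueError("metric balls require point data")
    g = network.to_networkx()
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xBA11]))
    centers = rng.integers(0, network.n, size=n_centers)
    out = []
    for r in ball_radii:
        if r <= 0:
            raise ValueError("radii must be positive")
        vals = []
        for c in centers:
            diff = ds.points - ds.points[int(c)]
            members = np.flatnonzero(np.einsum("ij,ij->i", diff, diff) <= r * r)
            if len(members) < 3:
                warnings.warn(f"ball of radius {r} holds < 3 nodes; skipped")
                continue
            vals.append(nx.average_clustering(g.subgraph(members.tolist())))
        out.append(float(np.mean(vals)) if vals else math.nan)
    return np.asarray(out)


@dataclass
class IntermodularLinks:
    count: int
    fraction: float
    endpoint_ranks: np.ndarray  # insertion ranks of intermodular-edge endpoints


def count_intermodular_links(network: GHNetwork, labels) -> IntermodularLinks:
    """Edges whose endpoints carry different cluster labels.

    ``labels`` is per-node (node index = insertion rank); use
    ``network.node_labels(...)`` to map labels given in original dataset
    order.  In clustered GH networks intermodular links are scarce and sit
    on the earliest-inserted nodes — the rich club is what stitches the
    modules together.
    """
    labels = np.asarray(labels)
    if len(labels) != network.n:
        raise ValueError("labels must cover all nodes")
    e = network.edges()
    if len(e) == 0:
        return IntermodularLinks(0, 0.0, np.empty(0, dtype=np.int64))
    inter = labels[e[:, 0]] != labels[e[:, 1]]
    count = int(inter.sum())
    ranks = e[inter].ravel()
    return IntermodularLinks(count, count / len(e), ranks)


# ---------------------------------------------------------------------------
# Stretch and hop bounds
# ---------------------------------------------------------------------------


@dataclass
class StretchResult:
    mean_stretch: float
    n_used: int
    n_failed: int
    ratios: np.ndarray


def stretch(network: GHNetwork, pairs) -> StretchResult:
    """Mean ratio of greedy hops to BFS shortest-path hops.

    Failed greedy searches are excluded from the mean and counted
    separately.  BFS distances come from single-source sweeps over the
    sparse adjacency, grouped by start node.
    """
    pairs = np.asarray(pairs)
    csr = network.to_csr()
    by_start: dict[int, list] = {}
    results: dict[tuple, SearchResult] = {}
    n_failed = 0
    for s, t in pairs:
        r = greedy_search(network, int(s), int(t))
        if r.success and r.hops > 0:
            results[(int(s), int(t))] = r
            by_start.setdefault(int(s), []).append(int(t))
        elif not r.success:
            n_failed += 1
    ratios = []
    for s, targets in by_start.items():
        bfs = sparse.csgraph.dijkstra(csr, unweighted=True, indices=s)
        for t in targets:
            sp = bfs[t]
            if not np.isfinite(sp):
                raise ValueError(f"nodes {s} and {t} are disconnected")
            ratios.append(results[(s, t)].hops / sp)
    ratios = np.asarray(ratios)
    return StretchResult(
        mean_stretch=float(np.mean(ratios)) if len(ratios) else math.nan,
        n_used=len(ratios),
        n_failed=n_failed,
        ratios=ratios,
    )


def hop_upper_bound_check(network: GHNetwork, pairs) -> tuple[float, float, bool]:
    """Mean greedy hops vs the analytic bound 2·log2(n)."""
    st = navigation_stats(network, pairs)
    bound = 2.0 * math.log2(network.n)
    return st.mean_hops, bound, bool(st.mean_hops <= bound)
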