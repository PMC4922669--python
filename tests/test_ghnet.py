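"""Construction: exact, approximate, and preferential attachment."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ghnav import (
    ConstructionConfig,
    GHNetwork,
    PointSet,
    build,
    build_approx,
    build_exact,
    build_pa,
    knn_search,
    make_clustered_points,
    make_uniform_points,
    measure_recall,
    navigation_stats,
    sample_pairs,
)
from ghnav.ghnet import _select_smallest
from ghnav.oracles import brute_force_knn


def insertion_recall(net: GHNetwork, M: int) -> float:
    """Recall of each node's insertion-time neighbor list vs brute force."""
    ds = net.dataset
    recs = []
    for i in range(M + 1, net.n):
        dist = np.sqrt(ds.prefix_sqdists(i))
        truth = set(_select_smallest(dist, M).tolist())
        found = set(j for j in net.adjacency[i] if j < i)
        recs.append(len(found & truth) / M)
    return float(np.mean(recs))


# -- exact construction -----------------------------------------------------


def test_two_elements_single_edge():
    net = build_exact(make_uniform_points(2, 2, seed=0), ConstructionConfig(M=5))
    assert net.n_edges == 1 and net.adjacency == [[1], [0]]


@given(st.integers(5, 60), st.integers(1, 8), st.integers(0, 3))
@settings(max_examples=25)
def test_edge_count_identity(n, M, seed):
    """|E| = sum_i min(i, M) for every exact build, any seed."""
    net = build_exact(
        make_uniform_points(n, 2, seed=seed), ConstructionConfig(M=M, seed=seed)
    )
    assert net.n_edges == sum(min(i, M) for i in range(n))


def test_sorted_1d_insertion_gives_path_graph():
    pts = PointSet(points=np.linspace(0, 0.9, 10).reshape(-1, 1), d=1)
    net = build_exact(pts, ConstructionConfig(M=1, shuffle=False))
    assert net.adjacency == [[1]] + [[i - 1, i + 1] for i in range(1, 9)] + [[8]]


def test_adjacency_symmetric_and_prefix_connected(gh1k):
    for i, nbrs in enumerate(gh1k.adjacency):
        assert all(i in gh1k.adjacency[j] for j in nbrs)
        if i > 0:  # a link to an earlier node => every prefix is connected
            assert min(nbrs) < i
        assert len(nbrs) >= min(i, gh1k.M)


def test_seeded_determinism():
    pts = make_uniform_points(300, 2, seed=4)
    a = build_exact(pts, ConstructionConfig(M=4, seed=4))
    b = build_exact(pts, ConstructionConfig(M=4, seed=4))
    assert a.adjacency == b.adjacency
    c = build_exact(pts, ConstructionConfig(M=4, seed=5))
    assert a.adjacency != c.adjacency


def test_build_rejects_degenerate_input():
    with pytest.raises(ValueError):
        build(make_uniform_points(1, 2, seed=0), ConstructionConfig(M=2))


# -- approximate construction ----------------------------------------------


def test_tiny_approx_equals_exact():
    """With n <= M+1 the searched graph is complete, so approx == exact."""
    pts = make_uniform_points(6, 2, seed=7)
    exact = build_exact(pts, ConstructionConfig(M=8, seed=7))
    approx = build_approx(pts, ConstructionConfig(M=8, mode="approximate", seed=7))
    assert exact.adjacency == approx.adjacency


def test_approx_insertion_recall_above_floor():
    pts = make_uniform_points(1000, 2, seed=7)
    net = build_approx(pts, ConstructionConfig(M=5, mode="approximate", seed=7))
    assert insertion_recall(net, 5) >= 0.95


def test_approx_matches_exact_navigation():
    """Success ratio of greedy search is insensitive to approximate insertion."""
    pts = make_uniform_points(10_000, 2, seed=21)
    exact = build_exact(pts, ConstructionConfig(M=12, seed=21))
    approx = build_approx(pts, ConstructionConfig(M=12, mode="approximate", seed=21))
    pairs = sample_pairs(exact, 2000, seed=22)
    se = navigation_stats(exact, pairs).success_ratio
    sa = navigation_stats(approx, pairs).success_ratio
    assert abs(se - sa) < 0.01


def test_clustered_approx_recall_above_paper_floor():
    """Insertion recall stays above 0.95 on strongly clustered 2D data."""
    pts = make_clustered_points(10_000, 2, 10, spread=0.01, seed=11)
    net = build_approx(pts, ConstructionConfig(M=5, mode="approximate", seed=11))
    assert insertion_recall(net, 5) >= 0.95


# -- preferential attachment ------------------------------------------------


def test_kc_at_most_M_reproduces_plain_network():
    """k_c <= M saturates every candidate equally: no preference at all."""
    pts = make_uniform_points(3000, 2, seed=3)
    plain = build_exact(pts, ConstructionConfig(M=8, seed=3))
    pa = build_pa(pts, ConstructionConfig(M=8, pa_enabled=True, k_c=8, seed=3))
    assert plain.adjacency == pa.adjacency


def test_pa_grows_hubs_faster_than_base():
    """Max degree separates monotonically across a size ladder (2 seeds)."""
    ratios = []
    for n in (2000, 8000, 32_000):
        r = []
        for seed in (0, 1):
            pts = make_uniform_points(n, 2, seed=seed)
            base = build_exact(pts, ConstructionConfig(M=12, seed=seed))
            pa = build_pa(pts, ConstructionConfig(M=12, pa_enabled=True, seed=seed))
            assert pa.degrees.max() > base.degrees.max()
            r.append(pa.degrees.max() / base.degrees.max())
        ratios.append(np.mean(r))
    assert ratios[0] < ratios[1] < ratios[2]


def test_pa_requires_vector_data():
    from ghnav import make_random_strings

    with pytest.raises(ValueError):
        build_pa(
            make_random_strings(10, "ab", 2, 4, seed=1),
            ConstructionConfig(M=2, pa_enabled=True),
        )


def test_base_degree_tail_is_exponential(gh100k):
    """Log-survival of degrees above 2M is linear (R^2 >= 0.98)."""
    from scipy.stats import linregress

    deg = gh100k.degrees
    tail = np.sort(deg[deg >= 2 * gh100k.M])
    uniq, counts = np.unique(tail, return_counts=True)
    surv = 1.0 - np.cumsum(counts) / len(tail) + counts / len(tail)
    keep = surv > 0
    fit = linregress(uniq[keep], np.log(surv[keep]))
    assert fit.rvalue**2 >= 0.98


# -- query-time search ------------------------------------------------------


def test_knn_exhaustive_when_K_is_network_size(gh1k):
    with pytest.warns(UserWarning):
        res = knn_search(gh1k, 17, gh1k.n + 5, n_trials=2, seed=0)
    truth = brute_force_knn(gh1k.dataset, 17, gh1k.n)
    assert np.array_equal(res, truth)


def test_knn_recall_with_calibrated_trials(gh1k):
    recalls = [
        measure_recall(
            knn_search(gh1k, q, 10, n_trials=8, seed=q),
            brute_force_knn(gh1k.dataset, q, 10),
        )
        for q in range(50)
    ]
    assert np.mean(recalls) >= 0.95


def test_knn_k1_single_trial_equals_greedy_terminal(gh1k):
    from ghnav.ghnet import _graph_knn
    from ghnav.navigate import greedy_search

    rng = np.random.default_rng(0)
    for _ in range(100):
        enter = int(rng.integers(gh1k.n))
        target = int(rng.integers(gh1k.n))
        union = _graph_knn(
            gh1k.dataset, gh1k.adjacency, gh1k.degrees, gh1k.n,
            lambda nodes: gh1k.dataset.dists(nodes, target), 1, 1,
            np.random.default_rng(1), enter=enter,
        )
        knn_term = min((k, v) for v, k in union.items())[1]
        assert knn_term == greedy_search(gh1k, enter, target).terminal


@pytest.mark.parametrize(
    "found,truth,expected",
    [
        ([1, 2, 3], [1, 2, 3], 1.0),
        ([4, 5], [6, 7], 0.0),
        (["a", "b", "c", "d"], ["a", "b", "x", "y"], 0.5),
    ],
)
def test_measure_recall(found, truth, expected):
    if isinstance(found[0], str):
        found = [hash(x) % 97 for x in found]
        truth = [hash(x) % 97 for x in truth]
        expected = len(set(found) & set(truth)) / 4
    assert measure_recall(found, truth) == expected


# -- serialization ----------------------------------------------------------


def test_graph_files_roundtrip(tmp_path):
    pts = make_uniform_points(60, 2, seed=2)
    net = build_exact(pts, ConstructionConfig(M=3, seed=2))
    edge_path = tmp_path / "net.edges.tsv"
    gml_path = tmp_path / "net.graphml"
    net.write_edgelist(edge_path)
    net.write_graphml(gml_path)

    edges, meta = GHNetwork.read_edgelist(edge_path)
    assert len(edges) == net.n_edges and meta["M"] == "3"

    back = GHNetwork.read_graphml(gml_path, dataset=pts)
    assert back.adjacency == net.adjacency
    assert back.M == 3 and back.mode == "exact"
    assert np.array_equal(back.order, net.order)
    # embedded coordinates alone also reconstruct a usable network
    coords_only = GHNetwork.read_graphml(gml_path)
    assert np.allclose(coords_only.dataset.points, net.dataset.points)
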