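"""Navigability analyses: scaling laws, tail fits, rich club, modularity,
stretch."""

import math

import numpy as np
import pytest
import scipy.stats

from ghnav import (
    ConstructionConfig,
    UndefinedFitError,
    build,
    clustering_self_similarity,
    count_intermodular_links,
    degree_tail_fit,
    hop_upper_bound_check,
    link_length_exponent,
    make_uniform_points,
    navigation_stats,
    rich_club_connection_curve,
    rich_club_navigability_test,
    sample_pairs,
    scaling_experiment,
    stretch,
)
from ghnav.metrics import _fit_scaling


def _gh_builder(d, M, pa=False, k_c=math.inf):
    def make(n, seed):
        pts = make_uniform_points(n, d, seed=seed)
        return build(pts, ConstructionConfig(M=M, pa_enabled=pa, k_c=k_c, seed=seed))

    return make


# -- pair sampling ----------------------------------------------------------


def test_sample_pairs_contract(gh1k):
    pairs = sample_pairs(gh1k, 2000, seed=1)
    assert pairs.shape == (2000, 2)
    assert np.all(pairs[:, 0] != pairs[:, 1])
    assert pairs.max() < gh1k.n
    assert np.array_equal(pairs, sample_pairs(gh1k, 2000, seed=1))
    restricted = sample_pairs(gh1k, 100, seed=2, restrict_to_first=50)
    assert restricted.max() < 50
    # restricting to the whole network is the unrestricted distribution
    assert np.array_equal(
        sample_pairs(gh1k, 100, seed=3),
        sample_pairs(gh1k, 100, seed=3, restrict_to_first=gh1k.n),
    )


def test_sample_pairs_rejects_single_node(complete_graph5):
    with pytest.raises(ValueError):
        sample_pairs(complete_graph5, 10, restrict_to_first=1)


def test_navigation_stats_complete_graph(complete_graph5):
    pairs = [(i, j) for i in range(5) for j in range(5) if i != j]
    st = navigation_stats(complete_graph5, np.array(pairs))
    assert st.success_ratio == 1.0 and st.mean_hops == 1.0


# -- scaling ----------------------------------------------------------------


def test_base_hops_scale_logarithmically():
    res = scaling_experiment(
        _gh_builder(2, 12), [1000, 3162, 10_000, 31_623], "hops",
        seeds=(0,), n_pairs=500,
    )
    assert res.model == "linear-in-logN"
    assert res.r_squared >= 0.98
    assert res.slope > 0


def test_pa_computations_scale_as_power_law():
    res = scaling_experiment(
        _gh_builder(2, 12, pa=True), [1000, 3162, 10_000, 31_623], "computations",
        seeds=(0,), n_pairs=500,
    )
    assert res.model == "power-law"
    assert res.fits["power-law"][2] > res.fits["linear-in-logN"][2]


def test_hop_slope_decays_with_cutoff():
    """Raising k_c above M sharply reduces the greedy hop slope."""
    slopes = []
    for k_c in (12.0, 48.0, math.inf):
        r = scaling_experiment(
            _gh_builder(2, 12, pa=True, k_c=k_c), [1000, 3162, 10_000], "hops",
            seeds=(0,), n_pairs=400,
        )
        slopes.append(r.fits["linear-in-logN"][0])
    assert slopes[0] > slopes[1] > slopes[2]


def test_fit_scaling_reports_tie():
    model, _, _, _ = _fit_scaling([10, 100], [1.0, 2.0])  # two points: both R^2 = 1
    assert model == "tie"


# -- degree tails -----------------------------------------------------------


def test_powerlaw_mle_consistency_within_3se():
    rng_draws = scipy.stats.zipf.rvs(2.2, size=30_000, random_state=7)
    fit = degree_tail_fit(rng_draws, "power_law")
    se = (fit.exponent - 1) / math.sqrt(len(rng_draws))  # asymptotic MLE s.e.
    assert abs(fit.exponent - 2.2) <= 3 * se + 0.05


def test_exponential_tail_beats_power_law_on_geometric_data():
    geo = np.random.default_rng(1).geometric(0.2, size=50_000)
    pl = degree_tail_fit(geo, "power_law", k_min=1)
    ex = degree_tail_fit(geo, "exponential", k_min=1)
    assert ex.goodness < pl.goodness


def test_tail_fit_rejects_constant_degrees():
    with pytest.raises(UndefinedFitError):
        degree_tail_fit(np.full(1000, 7), "power_law")
    with pytest.raises(UndefinedFitError):
        degree_tail_fit(np.full(1000, 7), "exponential")


def test_exponential_rate_matches_survival_slope(gh10k):
    from scipy.stats import linregress

    fit = degree_tail_fit(gh10k, "exponential")
    deg = gh10k.degrees
    tail = np.sort(deg[deg >= fit.k_min])
    uniq, counts = np.unique(tail, return_counts=True)
    surv = 1.0 - np.cumsum(counts) / len(tail) + counts / len(tail)
    slope = -linregress(uniq[surv > 0], np.log(surv[surv > 0])).slope
    assert fit.exponent == pytest.approx(slope, rel=0.15)


# -- link lengths -----------------------------------------------------------


def test_link_length_rejects_degenerate_lattice(line4):
    # make all edges the same length: 0.0-0.4 and 0.6-1.0 only
    line4.adjacency = [[1], [0], [3], [2]]
    with pytest.raises(UndefinedFitError):
        link_length_exponent(line4)


def test_link_length_exponent_d1():
    net = _gh_builder(1, 9)(100_000, 4)
    fit = link_length_exponent(net)
    assert fit.alpha == pytest.approx(2.0, abs=0.3)


# -- rich club --------------------------------------------------------------


def test_rich_club_complete_and_empty(complete_graph5):
    rc = rich_club_connection_curve(complete_graph5)
    assert np.all(rc.probability[rc.n_pairs > 0] == 1.0)
    complete_graph5.adjacency = [[] for _ in range(5)]
    complete_graph5._adj_arrays = None
    empty = rich_club_connection_curve(complete_graph5)
    assert np.all(empty.probability == 0.0)


def test_rich_club_probability_grows_with_degree(gh10k):
    rc = rich_club_connection_curve(gh10k)
    probs = rc.probability[rc.n_pairs > 0]
    assert np.all(np.diff(probs) >= 0)
    assert probs[-1] > 10 * probs[0]


def test_rich_club_single_size_curves_coincide():
    res = rich_club_navigability_test(
        _gh_builder(2, 12), n_first=2000, sizes=[2000], seeds=(0,), n_pairs=200
    )
    assert res.hops_restricted == res.hops_all


def test_rich_club_is_size_independent():
    """Hops between early-rank pairs stay flat while all-pair hops grow."""
    res = rich_club_navigability_test(
        _gh_builder(2, 20), n_first=2000, sizes=[2000, 8000, 32_000],
        seeds=(0, 1, 2), n_pairs=300,
    )
    assert res.slope_restricted < res.slope_all
    assert abs(res.slope_restricted) < 0.15
    assert res.hops_all[-1] > res.hops_all[0]
    # flat to within 10% across a 16x size span
    assert res.hops_restricted[-1] == pytest.approx(res.hops_restricted[0], rel=0.10)


# -- self-similarity and modularity -----------------------------------------


def test_full_cube_ball_equals_global_clustering(gh1k):
    import networkx as nx

    vals = clustering_self_similarity(gh1k, [2.0], n_centers=3, seed=1)
    assert vals[0] == pytest.approx(nx.average_clustering(gh1k.to_networkx()))


def test_triangle_free_graph_has_zero_clustering(line4):
    assert np.all(clustering_self_similarity(line4, [2.0], n_centers=2) == 0.0)


def test_clustering_profile_is_self_similar(gh10k):
    vals = clustering_self_similarity(gh10k, [0.05, 0.1, 0.2, 0.5], n_centers=8, seed=2)
    assert (vals.max() - vals.min()) / vals.mean() < 0.20


def test_intermodular_links_trivial_cases(line4):
    same = count_intermodular_links(line4, [0, 0, 0, 0])
    assert same.count == 0 and same.fraction == 0.0
    bridge = count_intermodular_links(line4, [0, 0, 1, 1])
    assert bridge.count == 1 and bridge.fraction == pytest.approx(1 / 3)
    with pytest.raises(ValueError):
        count_intermodular_links(line4, [0, 0, 1])


def test_intermodular_links_sit_on_early_ranks(clustered10k):
    """Bridges between clusters are scarce and owned by the rich club."""
    from scipy.spatial.distance import pdist

    net, pts = clustered10k
    centroids = np.array([pts.points[pts.labels == c].mean(0) for c in range(10)])
    assert pdist(centroids).min() > 0.1  # well-separated clusters (precondition)
    res = count_intermodular_links(net, net.node_labels(pts.labels))
    assert 0 < res.fraction < 0.02
    assert np.median(res.endpoint_ranks) < 0.25 * np.median(np.arange(net.n))


# -- stretch and hop bound --------------------------------------------------


def test_stretch_complete_graph_is_one(complete_graph5):
    pairs = [(i, j) for i in range(5) for j in range(5) if i != j]
    res = stretch(complete_graph5, np.array(pairs))
    assert res.mean_stretch == 1.0


def test_stretch_at_least_one(gh1k):
    res = stretch(gh1k, sample_pairs(gh1k, 200, seed=9))
    assert np.all(res.ratios >= 1.0)


def test_hop_bound(gh1k):
    mean_hops, bound, ok = hop_upper_bound_check(gh1k, sample_pairs(gh1k, 200, seed=9))
    assert bound == pytest.approx(2 * math.log2(gh1k.n))
    assert ok and mean_hops <= bound
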