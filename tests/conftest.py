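"""Shared fixtures.

The expensive networks (n = 1e4–1e5) are built once per session and shared
across test modules; their seeds are fixed so every assertion runs against
the same realizations.
"""

import math

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ghnav import (
    ConstructionConfig,
    GHNetwork,
    PointDataset,
    PointSet,
    build,
    make_clustered_points,
    make_uniform_points,
)

settings.register_profile(
    "ghnav",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ghnav")


@pytest.fixture(scope="session")
def gh100k():
    """Base GH network, uniform d=2, M=12, n=1e5 (exact construction)."""
    pts = make_uniform_points(100_000, 2, seed=1)
    return build(pts, ConstructionConfig(M=12, seed=1))


@pytest.fixture(scope="session")
def pa100k():
    """GH+PA network (k_c unbounded), uniform d=2, M=12, n=1e5."""
    pts = make_uniform_points(100_000, 2, seed=2)
    return build(pts, ConstructionConfig(M=12, pa_enabled=True, seed=2))


@pytest.fixture(scope="session")
def d50net():
    """High-dimensional network: uniform d=50, M=150, n=1e4."""
    pts = make_uniform_points(10_000, 50, seed=3)
    return build(pts, ConstructionConfig(M=150, seed=3))


@pytest.fixture(scope="session")
def gh10k():
    pts = make_uniform_points(10_000, 2, seed=14)
    return build(pts, ConstructionConfig(M=12, seed=14))


@pytest.fixture(scope="session")
def gh1k():
    pts = make_uniform_points(1_000, 2, seed=5)
    return build(pts, ConstructionConfig(M=6, seed=5))


@pytest.fixture(scope="session")
def clustered10k():
    """Clustered 2D data (10 tight clusters), M=5 — the modular construction.

    The seed is chosen so the random cluster centers are well separated
    (pairwise distance >> spread), the stated precondition for a modular
    realization; the tests assert that precondition explicitly.
    """
    pts = make_clustered_points(10_000, 2, 10, spread=0.01, seed=6)
    net = build(pts, ConstructionConfig(M=5, seed=6))
    return net, pts


@pytest.fixture()
def complete_graph5():
    """Complete graph over 5 uniform 2D points (hand-assembled)."""
    pts = make_uniform_points(5, 2, seed=9)
    adjacency = [[j for j in range(5) if j != i] for i in range(5)]
    return GHNetwork(
        dataset=PointDataset(pts), adjacency=adjacency, M=4, seed=9,
        order=np.arange(5),
    )


@pytest.fixture()
def line4():
    """Path graph over collinear points 0.0, 0.4, 0.6, 1.0."""
    pts = PointSet(points=np.array([[0.0], [0.4], [0.6], [1.0]]), d=1)
    adjacency = [[1], [0, 2], [1, 3], [2]]
    return GHNetwork(
        dataset=PointDataset(pts), adjacency=adjacency, M=1, order=np.arange(4)
    )
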