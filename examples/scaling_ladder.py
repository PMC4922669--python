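"""Hop and cost scaling across network sizes: logarithmic vs power law.

For the base model, mean greedy hops grow linearly in log2(n).  For the
pure-PA variant the hop count grows more slowly, but the number of distance
computations per search grows as a power of n — the scale-free shortcut is
paid for in information-extraction locality.
"""

import math

from ghnav import ConstructionConfig, build, make_uniform_points, scaling_experiment


def builder(pa):
    def make(n, seed):
        pts = make_uniform_points(n, 2, seed=seed)
        return build(pts, ConstructionConfig(M=12, pa_enabled=pa, seed=seed))
    return make


sizes = [1000, 3162, 10_000, 31_623]

hops = scaling_experiment(builder(False), sizes, "hops", n_pairs=500)
print(f"base GH hops:   {[round(m, 2) for m in hops.means]}")
print(f"  best model: {hops.model}, slope {hops.slope:.2f} per log2(n), "
      f"R^2={hops.r_squared:.4f}")

cost = scaling_experiment(builder(True), sizes, "computations", n_pairs=500)
print(f"GH+PA cost:     {[round(m) for m in cost.means]}")
print(f"  best model: {cost.model}, exponent {cost.slope:.2f}, "
      f"R^2={cost.r_squared:.4f}")
print("A 0.5 exponent matches hub-degree growth n^(1/(gamma-1)) at gamma~3: "
      "greedy routing through hubs must scan them.")
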