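"""Why hop count alone misleads: the star-graph demonstration.

With an effective distance that discounts degree exponentially, every
greedy route on a star graph goes leaf -> hub -> leaf: two hops at any
size.  But each search scans the hub's entire neighborhood, so the cost in
distance computations grows linearly with n.
"""

from ghnav.navigate import star_graph_demo

for n in (50, 100, 200, 400):
    _, hops, comps = star_graph_demo(n, a=10.0, seed=0)
    print(f"n={n:4d}: mean hops {hops.mean():.1f}, "
          f"mean distance computations {comps.mean():.1f}")
print("Hops stay at 2 while cost grows ~n: an 'ideal' navigable network by "
      "path-length measures, with the worst possible information-extraction "
      "locality.")
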