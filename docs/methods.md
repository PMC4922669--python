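# Methods

## The model

A growing homophilic (GH) network is built over an ordered set of elements
from a metric space. Elements are inserted one at a time in seeded random
order; each new element links bidirectionally to its `M` nearest
already-inserted elements. `M` is the model's single core parameter. Because
node indices equal insertion ranks, "element age" is readable off the index:
the earliest-inserted nodes accumulate degree and long links, forming the
rich club that later routing exploits.

Two construction modes are provided:

- **exact** — each insertion brute-forces the inserted prefix
  (`n(n−1)/2` distance evaluations in total);
- **approximate** — each insertion finds its neighbors by navigating the
  partially built graph itself with a dynamic-candidate-list search: start
  at a random enter node, keep the `M` closest elements discovered, expand
  the closest unexpanded list member until every list member is expanded,
  union over several restarts. The restart count is doubled (from 1, cap
  64) until recall on a 50-query probe against brute force reaches
  `recall_floor` (default 0.95), and recalibrated each time the network
  grows tenfold.

The **preferential-attachment (PA) variant** replaces the plain metric in
neighbor selection by the degree-normalized distance

    Δ_k = Δ / max(1, min(k, k_c))^(1/d)

where `k` is the candidate's degree at insertion time, `d` the vector-space
dimension and `k_c` the saturation degree. `k_c = ∞` produces a scale-free
degree tail with exponent near 3; finite `k_c` truncates it exponentially;
`k_c ≤ M` removes the preference entirely (every candidate already has
degree ≥ M, so the divisor is a constant — the builders reproduce the plain
network bit for bit in that case, which is tested). Candidate degrees are
frozen per insertion: all `M` links of one insertion are chosen under the
pre-insertion degrees and committed together.

## Routing and the locality measure

Greedy search moves, at each step, to the neighbor closest to the target,
and only if that neighbor is strictly closer than the current node; it
terminates at a local minimum, which equals the target exactly when the
search succeeds. Strict descent guarantees termination without a visited
set. Ties go to the lowest insertion rank (adjacency lists are stored
ascending); for string data exact ties are avoided at the source by adding
a small deterministic jitter to the edit distance (below).

Every distance evaluation is charged to a counter; the *information
extraction locality* of a search is its number of distance computations,
which is the search's true algorithmic cost and is distinct from its hop
count. A search's reported computation count equals the summed neighborhood
sizes of the nodes it expanded; the walker's own running distance to the
target is carried from the previous step rather than recomputed, and the
start node's distance is computed outside the counter (the searcher is
assumed to know where it stands). This bookkeeping makes the counter
cross-check exact in tests.

The modified greedy search ranks neighbors by the degree-normalized
distance instead (success still judged on the true target). On tightly
clustered data it multiplies the success ratio of plain greedy several
times over (≈ 0.77 vs ≈ 0.20 on the defaults below), because routes escape
the start cluster through the rich club, whose early members hold the few
intermodular links. A single normalized descent can still terminate on a
high-degree hub whose neighbors all look worse — this is why the package
asserts a large qualitative improvement rather than near-perfect success
for this router.

The star-graph demonstration pushes degree preference to its extreme: with
effective distance `Δ·exp(−a·k)` every route on a star goes leaf → hub →
leaf — two hops at any size — but each search scans the hub's whole
neighborhood, so its cost grows linearly with `n`. The implementation works
in log-domain (`log Δ − a·k`) because the literal product underflows to
zero once `a·k` exceeds ~700, and a zero effective distance at the hub
would defeat the strict-descent stop rule. Constant hops at linear cost is
the argument for measuring locality, not hops alone.

## Synthetic data

- **Uniform points**: i.i.d. uniform in `[0,1]^d`, L2 metric. These are the
  study conditions for all scaling results; per-dimension `M` values follow
  the navigation experiments (9, 12, 20, 25, 150 for d = 1, 2, 3, 5, 50).
- **Clustered points**: cluster centers uniform in the cube; members
  scattered isotropically (Gaussian, scale `spread`, default 0.01) with
  out-of-cube draws resampled (clipped only after 100 failures, keeping the
  in-cube invariant unconditional). Defaults: 10 clusters, `M = 5` — chosen
  as a configuration whose intermodular link fraction (~0.1–0.2 % of edges,
  concentrated on early ranks) reproduces the qualitative modular picture;
  the exact cluster geometry behind the published count of 30 intermodular
  links is not printed anywhere, so only the qualitative structure is
  asserted.
- **Random strings**: uniform lengths over `[min_len, max_len]`, uniform
  characters, under a Damerau–Levenshtein distance (restricted variant,
  adjacent transpositions cost 1) plus a deterministic jitter in
  `[0, jitter_scale)` hashed from the unordered pair. The jitter makes an
  integer metric tie-free for greedy routing while staying symmetric and
  reproducible; `jitter_scale = 0.1` (any value < 0.5 preserves the
  ordering of distinct base distances; the magnitude is otherwise
  inconsequential and was fixed once). Random strings stand in for a large
  real word list: they exercise the integer-metric code paths and the
  jitter contract, but their distance distribution is narrower than real
  vocabulary, so string-space results here are functional checks, not
  reproductions of word-dataset statistics. A user-supplied plain-text word
  list (one word per line) can be loaded into a `StringSet` instead.

## Analyses and numerical choices

**Scaling fits.** Mean hops (or distance computations) over seeded pair
samples are fitted both linearly in `log2 n` and on log-log axes; the model
with higher R² is reported, exact ties reported as ties, with both fits
retained. Base-model hops fit linear-in-log (R² > 0.99 on a
1e3–3e4 ladder, slope ≈ 1.1 per doubling at d=2, M=12); pure-PA distance
computations fit a power law (exponent ≈ 0.5, consistent with the maximum
degree growing as `N^(1/(γ−1))` at γ ≈ 3).

**Degree tails.** The exponential family is fitted by discrete geometric
MLE on the excess over `k_min` (default `2M`); the reported rate agrees
with the log-survival slope to a few percent. The power-law family uses
exact discrete MLE (zeta-function likelihood, numerically maximized) with
`k_min` selected by minimizing the KS distance between the empirical and
fitted tails, candidates restricted to tails of at least 100 points. On
1e5 synthetic zeta draws with exponent 2.5 the estimator lands within
±0.1.

**Link lengths.** Edge lengths are log-binned (40 bins) and the density
fitted by least squares on log-log axes over a central window: lengths
below the final M-th-neighbor scale `(M/n)^(1/d)` are excluded (links
shorter than that are still being laid down when growth stops, so their
density has not reached the stationary power law), as is the top 0.1 % of
lengths (cube-boundary truncation) and bins with ≤ 5 edges. The window was
chosen by inspecting local log-log slopes of the density at d = 1 and
d = 2, n = 1e5, *before* freezing the defaults; both dimensions then give
α within 0.05 of d + 1.

**Rich club.** The connection-probability curve is computed exactly, not
sampled: pairs are binned by their smaller endpoint degree (log-spaced
bins), pair counts per bin follow from the degree histogram, and connected
pairs are counted from the edge list. The navigability probe compares mean
hops for pairs drawn from the first `n_first` insertion ranks against
all-pair hops across a size ladder, with identical pair seeds so a
single-size ladder makes the two curves coincide exactly.

**Self-similarity.** For each ball radius, centers are sampled uniformly
from the point set and the mean local clustering coefficient of the
ball-induced subgraph is averaged over centers; balls with fewer than 3
nodes are skipped with a warning. On uniform-data networks the profile
varies by less than 20 % over a decade of radii.

**Stretch.** Mean over pairs of greedy hops divided by BFS shortest-path
hops, failures excluded and counted separately; BFS distances come from
single-source sweeps over the sparse adjacency, grouped by start node.
Measured values at d=2, M=12 rise 1.35 → 1.65 → 1.86 across
n = 1e3, 1e4, 1e5, approaching the predicted limit of 2 from below. A
linear extrapolation of these values against `1/log n` is *not* used as a
limit estimate: across this ladder the local slope in `1/ln n` still
steepens (−8.6 to −11.1), i.e. the regime is pre-asymptotic and the linear
model misspecified, so its intercept (~2.6) overshoots; the package
reports the largest-size measurement alongside the monotonicity check
instead.

## Problem sizes

Default experiment sizes were chosen for workstation scale: exact
constructions up to n = 1e5 (d ≤ 2) and n = 1e4 (d = 50), pair samples of
1e3–1e4, stretch ladders `{1e3, 1e4, 1e5}`, scaling ladders spanning 1.5
decades. The model's asymptotic claims (hop bound `2·log2 N`, stretch → 2)
are checked at these sizes; multi-million-element regimes are reachable
through the approximate builder but are not part of the default runs.

## Known limitations

- The approximate builder's trial calibration assumes pending elements are
  statistically exchangeable with future queries; on adversarially ordered
  data the probe could mislead it.
- `k_c` only saturates the distance normalization; nodes are not capped and
  keep receiving links past `k_c` (the truncation of the degree tail is
  statistical, not hard).
- Exact discrete Delaunay construction is provided only in 1D; in higher
  dimensions the M-nearest rule is an approximation whose failure modes
  are measured (success ratio), not bounded.
- The degree-normalized single-descent router has no success guarantee on
  modular data; the dynamic-list search with restarts is the reliable
  high-recall primitive.
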