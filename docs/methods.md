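# Methods

## Cluster definition

A similarity graph `G(V, E)` carries weights `w(e)` in `[0, 1]` (percent
similarities divided by 100). Given thresholds `0 < W < U < 1` and
tolerance `0 < s < 1`, edges split into strong `E_U = {e : w(e) ≥ U}` and
weak `E_W = {e : W ≤ w(e) < U}`; everything below `W` is discarded. A
vertex set `C` with `|C| = N` is a valid cluster iff

1. the induced subgraph on `C` restricted to `E_U` is connected (the
   *backbone*; a singleton counts as connected), and
2. for every `v ∈ C`, the within-`C` degree counting edges of `E_U ∪ E_W`
   is at least `N − S` with `S = s·N + 1`, i.e. `deg(v) ≥ (1−s)·N − 1`.

The degree comparison is done in real arithmetic exactly as written — the
integer degree is compared against the real bound with no rounding of `S`
(a `1e-9` slack guards against float representation of the bound only).
Strong edges count toward the density level a fortiori: anything `≥ U` is
also `≥ W`.

Consequences used throughout as closed-form checks:

- a strong clique of any size `N` is valid for every `s` (degree `N−1 ≥
  (1−s)N − 1` iff `sN ≥ 0`);
- inside a strong path, the endpoints (degree 1) cap any valid sub-cluster
  at `N ≤ 2/(1−s)` — size 2 at `s = 0.25`. This is the machine-checkable
  form of chaining control;
- raising `W` (fixed `U`, `s`) only removes density edges, so it never
  creates a valid set that was invalid at the lower `W`.

## Parameters

| parameter | meaning | default | rationale |
|---|---|---|---|
| `U` | strong (backbone) similarity threshold | 0.7 | standard operating point for families diversifying within a radiation; higher `U` fragments, lower invites chaining pressure |
| `W` | weak (density) threshold; also the read-time filter | 0.6 | keeps a band of lower similarities purely as density support |
| `s` | proportional S-plex slack | 0.25 | caps path-shaped clusters at size 2 while letting a size-20 family tolerate 5 missing neighbours per member |
| `budget` | heuristic: max extensions sampled per growth step | none (exact) | any positive integer; output is always a subset of the exact-mode output |
| `reorder_every` | seed-order refresh interval (in seed removals) | 1000 | refreshing more often re-sorts by residual degree at some cost; affects which seed each cluster is grown from, never soundness |

Both thresholds are inclusive at their lower ends: `w = U` is strong,
`w = W` is weak. Pair files on the percent scale are auto-detected (any
value `> 1`) and divided by 100; an override flag forces either unit.

## Enumeration

For each seed `v`, a queue starts at `{v}`; a dequeued set `sg` is
recorded and, while `|sg|` is below the seed's size bound, extended by any
outside vertex joined by a strong edge to **any** member. An extension is
enqueued only if the extended set is itself valid. Duplicate member sets
are pruned (the frontier of a set does not depend on insertion order). A
configuration flag restores the stricter variant that extends only from
the most recently added vertex; it is off by default because it cannot
reach some valid sets (a star grown hub-first stalls at two vertices).

The size bound is `m = ⌊(d+1)/(1−s)⌋` for a seed of degree `d` over
`E_U ∪ E_W`: any cluster containing the seed has the seed's within-cluster
degree `≤ d`, so `N > m` would violate the density bound. The randomized
suite verifies the bound prunes nothing valid. An alternative bound
`⌊d·s + 1⌋` is available behind a flag for comparison only; it is not
implied by the density condition and collapses as `s → 0`.

Two structural facts, found by the oracle harness and kept as tests:

- **Non-hereditary validity.** Because the slack grows with `N`, a valid
  set may have no chain of valid subsets: a strong 4-cycle at `s = 0.25`
  is valid (all degrees 2 ≥ 2) but every 3-subset is a path whose
  endpoints fail (1 < 1.25). Growth through valid intermediates therefore
  cannot reach it. On random 9-vertex graphs roughly a quarter have at
  least one such unreachable set. The enumeration is sound (never emits an
  invalid set, verified against brute-force subset enumeration); the
  unreachable-set count is reported, not hidden.
- **Order sensitivity.** The outer driver grows each cluster from its
  first-processed member; reachability can differ between members, so the
  candidate family depends (mildly) on the seed order and hence on
  `reorder_every`. Soundness and the singleton cover do not.

In heuristic mode, when a growth step has more admissible extensions than
the budget, that many are sampled uniformly without replacement with the
seeded generator; output member sets are a subset of exact-mode output,
and fixed seeds give byte-identical candidate lists.

## Decomposition

Greedy local optimisation: enumerate candidates on the residual graph,
emit the largest, delete its vertices, repeat until only singletons
remain. Deleting non-members changes nothing inside a cluster (both
criteria are induced-subgraph properties), so emitted clusters are valid
in the residual and original graphs alike, and sizes are non-increasing.
Ties are broken deterministically: member count, then total internal
weight of edges `≥ W`, then lexicographically smallest sorted member list.
Vertices never absorbed — including genes whose only similarities fell
below the `W` filter — are reported as singletons.

## Size distributions

Families are tallied into inclusive bins, by family count and by gene
count; proportions are over included families/genes. Singletons are
excluded by default. The default scheme is per-size bins 2–7, then 8-10,
11-13, 14-17, 18-21, 22-26, and an open-ended 27+; only the 8-10, 22-26
and 27+ boundaries are fixed by convention, the intermediate bins are a
configurable choice. The two-way comparison reports per-bin proportion
differences and flags an input whose proportions are strictly lower in
every bin from the moderate bin (default 8-10) upward, separately for
family and gene proportions. MCL-format cluster files flow through the
same code path, so method comparisons share all downstream arithmetic.

## Synthetic fixtures

The generator plants clusters of requested sizes: each within-cluster pair
gets a strong edge with probability `p_strong` (weight uniform in
`[U, 1]`), else a weak edge with probability `p_weak` (uniform in
`[W, U)`). A planted cluster is rejection-sampled until it validates under
the model's own parameters, so the ground truth is valid by construction;
infeasible settings fail after a bounded number of attempts. Chain
segments are pure strong-edge paths with no weak chords — the adversarial
case for chaining. Background noise edges between groups appear with a
small probability, half below `W` (dropped at read time) and half in the
weak band, never strong — so spurious backbone connections cannot occur by
construction, and noise stresses only the density criterion. Everything is
driven by one seeded generator; identical models give identical graphs.

What the fixtures do **not** emulate about real similarity data: the
skewed similarity spectra of genome self-comparisons (e.g. the pile-up of
low-similarity duplicate pairs just above `W`), domain-sharing between
families (which in real data produces weak *and strong* cross-family
edges), tandem arrays, and fragmented gene models. Passing recovery tests
therefore demonstrates correctness of the algorithmics under the model's
assumptions, not field performance on any particular genome.

## Problem sizes and numerical choices

Test and acceptance runs use graphs of 4–12 vertices wherever the
brute-force subset oracle is involved (subset enumeration is exponential;
12 vertices means 4095 subsets per graph), 200 randomized graphs for the
oracle harness, 20 replicates for noisy recovery, and planted fixtures of
3–8-vertex clusters — sizes chosen so every claim is verified exhaustively
rather than spot-checked. Degenerate inputs: the empty graph decomposes to
nothing; an empty pair file is an empty graph, not an error; singleton-only
inputs give zero-total distributions with all proportions 0 (no division).

## Known limitations

- Exact enumeration is exponential in dense regions; use the heuristic
  budget for large genomes.
- The growth procedure's reachable family is a (measured) subset of all
  valid sets; decompositions choose among reachable candidates.
- Greedy largest-first is a local optimisation with no global guarantee.
- The reader accepts only numeric similarity columns; e-value-based inputs
  must be converted upstream.
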