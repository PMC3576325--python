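# Methods and design notes

## Data model

A *module* is a non-empty set of item IDs; a *clustering* is an ordered
list of modules that may overlap and may cover only part of the items; an
*ensemble* is an ordered list of `k` clusterings.  The item *universe* is
the union of all items in first-appearance order (modules are walked in
file order, items within a module in sorted order, so the universe is
deterministic).  Items a clustering leaves unassigned form its *grab bag* —
a first-class state, not an error, since partial coverage is normal for
density-seeded graph-clustering algorithms.

Module files use the MCL dialect (one module per line, whitespace-separated
IDs, `#` comments).  Duplicate IDs on a line are deduplicated with a
logged warning rather than rejected: tolerant ingestion matters more than
strictness for files assembled by hand.  Clustering names are file stems
and must be unique because they key the signature columns and band order.

### Overview statistics

Per clustering: module count, average module size `N/c` (with
`N = Σ|m_i|` membership slots), items clustered, percentage of clustered
items in more than one module, and the clustering entropy

    H = − Σ_i (|m_i|/N) · log2(|m_i|/N)   [bits].

Entropy is slot-normalized: an item in two modules contributes two slots.
For overlapping clusterings this overestimates the partition entropy (the
distribution no longer describes disjoint events); the statistic is still
reported because it stays comparable across clusterings of the same data.
Base-2 logs make the uniform cases integral (`c` equal modules give
exactly `log2 c` bits).

## Similarity metrics

Two items are *co-clustered* in a clustering iff they share at least one
module.  The pair-counting metrics (Jaccard, Rand, Fowlkes–Mallows,
Mirkin) are computed from the counts `n11, n10, n01, n00` of unordered
item pairs by co-membership in the two clusterings:

    Jaccard = n11/(n11+n10+n01)        Rand = (n11+n00)/C(n,2)
    FM      = n11/√((n11+n10)(n11+n01))   Mirkin = 2(n10+n01)/n²

Mirkin is reported normalized by `n²` so that it lies in [0, 1] and
heatmap coloring is scale-free.  Degenerate 0/0 cases (two all-singleton
clusterings) are defined as perfect agreement (1 for similarities, with FM
returning 0 when only one marginal is empty).

Unclustered items enter as singleton modules by default, keeping the pair
total `C(n,2)` constant across the ensemble so ladder cells are
comparable; the alternative `exclude` policy restricts the comparison to
items clustered in both clusterings.

Mutual information (bits), variation of information
`VI = H1 + H2 − 2·MI`, purity, inverse purity, and the size-weighted
best-F measure are computed from the membership-slot contingency table
`n_ij = |m_i ∩ m_j|`.  For overlapping clusterings this table is an
approximation (slots, not items); the pair-counting metrics handle overlap
exactly via the ≥1-shared-module rule.

## Co-cluster matrices

`A^K` is binary with `a_ij = 1` iff `i ≠ j` co-cluster in K; a pair
sharing two modules of one clustering still scores 1 — co-membership is a
fact, not a multiplicity.  `A⁺ = Σ_t A^{K_t}` has entries `0..k`.  The
diagonal is fixed at zero and excluded from the support count `z̄` (number
of non-zero strict-upper-triangle cells), which keeps the reordering
weights and density sums pure functions of item *pairs*.  Matrices are
dense numpy arrays throughout: at the scales this package targets (a few
thousand items) a dense integer matrix is tens of megabytes and every
downstream step is vectorized.

The pairs table's "signature" sort key reads the bit vector as a binary
number with the last clustering least significant, so ensembles extended
with a new clustering keep their relative order among old bits.

## Seriation

With the columns frozen in the current order, the cost of placing row `i`
at position `ℓ` is

    w(i, ℓ) = Σ_j a⁺_ij · |pos(j) − ℓ|,

i.e. rows are rewarded for sitting near their mass.  This weight is a
function of the *target position* `ℓ` and of the current column positions;
it is recomputed each iteration because applying the permutation
symmetrically moves the columns.  One linear assignment problem (LAP) per
iteration is solved either greedily (repeatedly take the globally cheapest
free row/position pair, ties broken by lowest row then position index) or
optimally with the Hungarian method (scipy's `linear_sum_assignment`).
The default pipeline runs one greedy pass and then Hungarian refinements,
up to `max_iter = 20` iterations — convergence is typically reached in
well under ten — stopping on no cost improvement or on revisiting a
previously seen permutation (tracked as a set of permutation tuples).

Iterated LAP is a local search and the result depends on the initial
order.  Matrices built from module files start in universe order, which
already places co-module items adjacently — a favorable and meaningful
start, and the default is a single deterministic run from it.  For
matrices whose input order carries no signal (externally shuffled or
randomized), `restarts > 0` runs additional searches from seeded random
permutations and keeps the result with the smallest envelope
(`Σ |pos(i) − pos(j)|` over non-zero cells), with assignment cost as
tie-break.  All tie-breaking is lexicographic, so the full procedure is
deterministic given (input, solver, max_iter, seed, restarts).

Quality is summarized by the bandwidth (max position distance over
non-zero cells) and envelope metrics.

## Cores

In the reordered matrix, the block `[p, q]` (1-based, inclusive) has sum
`s(p,q) = Σ_{p≤i<j≤q} a⁺_ij`, computed for all blocks in O(n²) via
`s(p, q+1) = s(p, q) + Σ_{i=p..q} a_{i,q+1}`, and density

    d(p, q) = s(p, q) / h,    h = q − p + 1.

The denominator is the number of *vertices* in the block, matching the
weighted-subgraph reading `d = |E(S)|/|V(S)|`: it is finite for singleton
blocks (`d(p,p) = 0`) and is the form under which the expected-density
null below is self-consistent.

The partition of positions 1..n into contiguous blocks maximizing
`Σ d` is found by the dynamic program
`D_opt(j) = max_{1≤i≤j} {D_opt(i−1) + d(i,j)}` with backtracking.
Singleton blocks are allowed (zero density; they never survive
filtering).  Ties prefer fewer blocks, then the earliest block start
scanned at each suffix — on an all-zero matrix the result is the single
block `[1, n]`.  Scores are compared exactly (floats derived from integer
sums); the DP is verified against exhaustive enumeration of all `2^(n−1)`
contiguous partitions at small n.

A block is reported as a core only if its density exceeds the uniform
null: with `w_avg = s(1,n)/z̄` the mean non-zero cell value and
`P(e) = z̄/C(n,2)` the edge probability,

    d_avg(p, q) = w_avg · P(e) · C(h,2)/h = s(1,n)·(h−1)/(n(n−1)).

The `C(n,2)` denominator in `P(e)` is what makes the null self-consistent:
the whole-matrix expectation `d_avg(1,n)` equals the observed global
density `s(1,n)/n` exactly, and a uniform all-pairs matrix yields no cores
at all.  An empty matrix (`z̄ = 0`) leaves the null undefined; no cores
are reported and a warning is logged.

*Cohesion* of a core against an undirected network is `E_in/E_out` (edges
inside versus edges crossing the boundary); an isolated core with internal
edges returns `+inf`, a core with no incident edges 0.  Cores are computed
on an explicitly reordered matrix passed in by the caller — the ordering
is never recomputed implicitly, so results are reproducible from the
ordering artifact alone.

## Parallel-partitions layout

Band order is a greedy chain: seed with the most similar clustering pair,
orient it so the member with the higher best similarity to the remaining
clusterings becomes the tail, then repeatedly append the clustering most
similar to the last added (ties lexicographic by name; distance metrics
are negated).  Within a band, modules are sorted by ascending displacement
rank `d(m) = Σ_{u∈m} i(u)` over matrix columns `i(u)` — the raw sum, not
the mean, is used even though it biases large modules toward late
positions, because it is the simpler invariant and module widths are
visible in the plot anyway.  Items within a module follow their matrix
column; the grab bag is always the trailing (gray) block and excluded
from ranking.  Overlapping modules duplicate their shared items in every
module they occur in, so per-band widths equal membership slots plus the
grab-bag size.

## Rendering

All views are SVG built by a small string-template writer with fixed
6-significant-digit number formatting, so identical inputs give
byte-identical files and figures can be asserted structurally (one `cell`
rect per non-zero matrix cell, one `ribbon` polygon per shared item per
adjacent band pair, one `bar` per statistic per clustering).  Matrix cells
ramp from light pink (`a⁺ = 1`) to saturated red (`a⁺ = k`); an optional
flag paints never-co-clustered cells black.  Core outlines are green; the
cohesion overlay is a centered blue square of side
`core_side · cohesion/(1+cohesion)`, a monotone map of `[0, ∞)` onto
`[0, 1)` so "bigger overlay = more isolated core" holds without clipping.
Each clustering keeps one stable hue across all views; overlapping
clusterings get striped fills.  PNG output is not implemented — SVG is
resolution-independent and diffable, and rasterization would add a heavy
dependency for no analytic value.

## Synthetic ensembles and oracles

`PlantedEnsembleSpec` defaults define the reference study conditions: 120
items, `k = 8` clusterings, five disjoint planted groups of sizes
(8, 12, 20, 5, 15) with supports (7, 6, 8, 6, 7), 5% background
reassignment noise, full coverage, no overlap, background modules of 3–15
items.  Each planted group appears as an exactly intact module in exactly
its support count of clusterings; noise, coverage and overlap apply only
to background items so intactness is guaranteed, not merely probable.
All randomness flows from one integer seed through a single generator.

What the generator does *not* emulate: realistic degree structure of PPI
networks, correlated errors between clusterings produced by similar
algorithms, hierarchically nested modules, and size distributions with
heavy tails.  Passing the recovery tests therefore shows that the pipeline
finds groups that genuinely co-cluster across most of an ensemble under
independent noise — not that any particular biological dataset contains
such groups.

The test oracles are independent brute-force implementations — an O(n²)
pair loop, an O(n⁴) block-sum loop, exhaustive `2^(n−1)` partition
enumeration, and `n!` assignment search — with enforced size limits
(n ≤ 200/20/12/7) and no shared helpers with the fast paths they check.

## Numerical and interface choices

* Output numbers use fixed 6-significant-digit formatting; TSVs are
  byte-stable across runs and platforms.
* Oracle comparisons assert at 1e-12 (pair counts are integers), VI
  identity at 1e-9, DP/LAP optimality at 1e-9.
* Exit codes: 0 success, 2 usage error, 1 data error.  The resolved run
  configuration is serialized as JSON into every output directory.
* `scripts/acceptance.py` and the heaviest tests run ensembles of 120–500
  items — sizes at which every pipeline stage completes in seconds while
  leaving planted structure non-trivial to recover.

## Known limitations

* Information-theoretic metrics on overlapping clusterings are
  slot-approximations (flagged above); only the pair-counting metrics
  treat overlap exactly.
* Seriation is a local search; a single run from an adversarial input
  order can leave a weakly supported group split.  Restarts mitigate but
  do not guarantee recovery, and with many restarts the selected ordering
  optimizes envelope, which for weak-support groups does not always
  coincide with block contiguity.
* Cores are contiguous and disjoint by construction; genuinely overlapping
  cores cannot be represented.
* The expected-density null assumes uniformly placed support cells; it is
  conservative for matrices whose background is itself blocky.
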