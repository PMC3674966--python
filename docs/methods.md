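# Methods

## Problem and scope

The package solves the classical Steiner tree problem on *unweighted*,
undirected, simple graphs: given *G* = (*V*, *E*) and terminals *S* ⊆ *V*
(|*S*| ≥ 2, all in one connected component), find a connected sub-graph
containing *S* with the fewest edges. Node IDs are opaque strings; there are
no edge weights, node scores or profits anywhere — the prize-collecting
variant is deliberately out of scope. Distances are hop counts, and two
facts about unweighted graphs are used throughout: every spanning tree is a
minimum spanning tree, and a spanning tree over *n* nodes has exactly
*n* − 1 edges.

## Algorithms

**Exact search** (`exact_steiner_tree`). Candidate sets *A* of non-terminals
are enumerated by increasing |*A*| (lexicographic within a size class); the
first *A* whose induced sub-graph on *S* ∪ *A* is connected (linear-time
BFS test) yields the optimum with |*S*| + |*A*| − 1 edges. Three admissible
prunings keep toy instances fast without affecting correctness: candidates
are restricted to the component containing *S*; at size class *k* any
non-terminal farther than |*S*| + *k* − 1 hops from every terminal is
dropped; and enumeration starts at *k* = max pairwise terminal distance
− |*S*| + 1, since a tree covering two terminals needs at least their
distance in edges. The worst case remains exponential in |*V* \ *S*|, so a
node-count guard (default 30, overridable) refuses hopeless inputs.

**Merged exact solutions** (`exact_merged_subgraph`). All minimal-size
candidate sets are collected and their induced sub-graphs merged. Every
edge of a connected graph lies on some spanning tree of it, so the union of
all minimal Steiner trees over a fixed node set *is* that node set's
induced sub-graph; merging induced sub-graphs therefore loses no edge of
any minimal tree.

**SP** (`sp_steiner`). Grow from a start terminal; repeatedly run a
multi-source BFS from the current sub-graph and attach the nearest
uncovered terminal along one shortest path; finish with a spanning tree and
iterated removal of non-terminal leaves. Restarted from `repeats` (default
10) random start terminals, keeping the smallest tree. The classical
guarantee |*E*′| ≤ (2 − 2/|*S*|) × optimum holds per run, hence for the
best-of-r result; for |*S*| = 2 the result is exactly one shortest path and
therefore optimal.

**KB** (`kb_steiner`). Each terminal starts as its own component; the pair
of components at minimum inter-component hop distance is merged along one
connecting shortest path until a single component remains, then the same
clean-up as SP. If a connecting path happens to touch a third component,
that component is absorbed in the same step, keeping the forest
node-disjoint. The method is fully deterministic.

**RSP** (`rsp_steiner`). Start from *G**, the union of *all* geodesics
between every terminal pair, and its spanning tree *T*. For `repeats`
(default 70) iterations, with equal probability attempt either removal of a
uniformly random non-terminal of *G** (rejected if *G** would disconnect)
or insertion of a uniformly random outside neighbor of *G** within
`max_len` hops of a terminal; a move is accepted only if the new spanning
tree is strictly smaller than *T*. Because a spanning tree over *n* nodes
always has *n* − 1 edges, a connectivity-preserving removal always shrinks
the tree by exactly one edge and is always accepted, while an insertion
alone can never be accepted under strict improvement. The insertion branch
is retained faithfully to the published procedure — it is attempted, draws
from the RNG, and is rejected — so RSP behaves as randomized
leaf-and-articulation thinning of *G**. `max_len = "auto"` uses the maximum
pairwise terminal distance, bounding insertions to plausibly useful nodes.

**ASP** (`asp_subgraph`). The baseline: union of one geodesic per unordered
terminal pair (the lexicographically smallest node sequence, starting from
the smaller terminal). Connected and terminal-covering but in general
neither a tree nor small. Note the asymmetry with RSP's *G**, which takes
*all* geodesics per pair; both choices are deliberate and documented here
because the two operations serve different roles (a baseline result vs. a
search space).

**STM** (`stm_merged`). The SP growth loop modified in two places: at each
step *all* terminals tied at the minimum distance are attached, each along
*all* of its geodesics to the current sub-graph (read off the BFS
predecessor DAG). One run is made from every terminal when |*S*| ≤
`repeats`, else from `repeats` random start terminals; each run is scored
by the edge count of its cleaned-up spanning tree, and the sub-graphs of
all runs attaining the minimum score are merged. `minimal_tree_size` is
that score. Merging all best runs (rather than keeping one) is a design
choice: the method's purpose is to expose the diversity of equally good
solutions, and each merged run contributes only sub-graphs containing a
tree of the reported size.

## Determinism and tie-breaking

Every method maps identical `(instance, config)` — seed included — to
identical output. Choices the procedures leave open are fixed as follows:
geodesics are the lexicographically smallest node sequence; spanning trees
are BFS trees rooted at the lexicographically smallest node with neighbors
visited in lexicographic order; SP's nearest-terminal ties are broken by
the run's seeded RNG (STM takes all ties — its defining change); SP's
best-of-r ties prefer smaller edge count, then higher terminal frequency,
then the lexicographically smallest edge set; KB's distance ties take the
smallest pair of component indices, components ordered by their
lexicographically smallest terminal.

Leaf-stripping is iterated to a fixed point rather than applied once: a
single pass can expose new degree-1 non-terminals, and further passes only
shrink the tree while preserving terminal coverage and connectivity.

## Simulation protocol

`random_walk_terminals` samples seed sets the way benchmark studies sample
"disease genes": a random walk from a uniform start node marks each *first*
visit a terminal with probability θ (default 0.5) until `n_terminals` are
collected. Terminal candidacy is evaluated on first visits only; re-flipping
on revisits would bias selection toward high-degree nodes beyond the walk's
own bias. Larger θ packs terminals closer together; the benchmark config
supports sweeping θ over e.g. {0.2, 0.5, 0.8}.

`sample_subgraph` produces small connected networks for exact comparisons:
a random walk absorbs each visited node's closed neighborhood (the node,
its incident edges, its neighbors) until at least `min_nodes` (default 30)
nodes are present, or the walk's component is exhausted, whichever comes
first — the exhaustion guard prevents an infinite loop on small components.

`generate_synthetic_network` stands in for a real interaction network at
desk scale: Barabási–Albert preferential attachment (default, 3 edges per
new node) reproduces the heavy-tailed degree distribution of
protein-interaction networks; Erdős–Rényi G(n, m) is available as a
homogeneous contrast. Only the largest connected component is returned.
What the generator does *not* emulate: the true network's size (~13,000
nodes and ~400,000 edges), its degree correlations, clustering and dense
core — so passing benchmarks show the methods' *relative* behavior
(ordering, significance directions), not the absolute sub-network sizes one
would obtain on a curated interactome.

`run_benchmark` gives every method the same terminal sets (one per
replicate, seeded deterministically from the master seed), records edge
count, terminal frequency and wall-clock runtime, and never aborts on a
method failure — failures become records with an `error` field. Runtime is
recorded but excluded from statistics, being hardware-dependent.
`compare_methods` runs two-sided paired Wilcoxon signed-rank tests per
method pair (pairing replicates by shared terminal set) with Holm's
step-down correction across the pairs at the same |*S*|; all-zero
difference vectors are reported as `identical` with no p-value. Two-sided
testing with a reported direction was chosen over one-sided tests so the
table does not presuppose which method wins. At least 6 complete pairs are
required — below that the exact two-sided signed-rank test cannot reach
p < 0.05 at all.

## Problem sizes used in tests and the acceptance script

Oracle cross-checks use 100 random connected graphs with ≤ 12 nodes and
2–5 terminals, where the independent edge-subset oracle is exhaustive. The
heuristic-ranking benchmark uses a 2,000-node scale-free network, θ = 0.5,
terminal sets of 5, 8, 20 and 50, and 20 replicates per size — a
deliberately scaled-down version of a full interactome study that keeps the
complete analysis under a minute while leaving the statistical comparisons
well-powered (exact signed-rank p ≈ 9 × 10⁻⁵ at n = 20 for a clean sweep).

## Known limitations

* The exact search and the brute-force oracle are exponential by nature;
  the guards (30 and 15 nodes) are there to fail fast, not to be raised
  casually.
* RSP's accepted moves are removals only (see above); its practical value
  over SP on hard instances is limited, and it is kept primarily as a
  faithful member of the benchmarked method family.
* ASP on large |*S*| is quadratic in the number of terminal pairs and grows
  the largest sub-graphs of all methods — that is its documented role as a
  baseline.
* Real interaction networks must be provided by the user as SIF or edge
  lists; the package does not download or merge pathway databases.
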