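# Methods

## The compound-graph model

`HierGraph` stores a mixed two-layer structure: a containment layer — a
forest of parent pointers in which every node has at most one parent and
only `container` nodes may have children — over an undirected, weighted
graph on the `leaf` nodes.  Edges are canonicalized to `(min, max)` id
order; re-adding a pair replaces the weight (last wins), and a pair
touching at least one container is stored on a separate *association*
layer, outside the hierarchy.  Deleting a container (`unnest`) promotes
its children to the grandparent and drops association edges whose
endpoint disappears; leaf-layer edges are never touched by containment
operations.  All tie-breaking throughout the package (component ties,
cluster-merge ties, container naming, iteration orders) is lexicographic
on node ids, so every result is reproducible without hidden randomness.

`nest(members)` places the new container under the former deepest common
ancestor of the members; an explicit `parent` may override the placement
and is validated against containment cycles.  `largest_connected_component`
induces the leaf subgraph on a subset and returns the biggest component,
ties broken by the smallest minimum member id (networkx supplies the
component enumeration; the test suite checks it against a hand-written
BFS).

## Clustering and superimposition

`build_dendrogram` is agglomerative complete linkage with Euclidean
distances: at each step the two clusters with the smallest maximum
pairwise distance merge.  The implementation uses the Lance–Williams
update for complete linkage (new inter-cluster distance = elementwise
max), which is exact for this criterion, and breaks exact ties by the
lexicographically smallest pair of cluster minimum labels.  The merge
table follows the standard convention: negative integers reference
leaves, positive integers prior merge steps.

Two cut metrics are supported.  `rootdist` counts integer merge depth
from the root (root merge = depth 0): the clusters of a cut at level `c`
are the maximal subtrees whose root merge sits at depth `c`; leaves that
detach nearer the root become singletons, and a cut deeper than the tree
yields all singletons.  `height` severs every merge above a real
threshold.  `threshold_for_k` returns the classic "k groups" threshold
(midpoint between the (k−1)-th and k-th largest merge heights); with tied
heights the group count may differ, which is inherent to the device.

`nest_dendrogram` maps a cut onto the graph: each cluster with ≥ 2
members becomes a container enclosing its leaves; for `nlev > 1` the
cluster's child subtrees (one merge-depth step down) become containers
nested inside it, recursively, stopping silently where the tree runs out
of depth.  Singleton clusters create no container and keep their prior
parent, so a fully degenerate cut leaves the graph unchanged.  Prior
containment of the re-parented leaves is replaced, and containers
emptied by the re-parenting are pruned — keeping them would leave
zero-member containers that the aggregation layer rightly rejects.

## Inter-module aggregation and styling

For containers A and B (neither nested in the other, both non-empty) the
module edge is `count = |{leaf edges with one endpoint under A, one under
B}|` and `weight = count / (|leaves(A)| × |leaves(B)|)`.  The bipartite
pair count is the only normalization that makes the weight a density in
[0, 1] with weight 1 exactly for a complete cross-bipartite pattern; a
container versus a single leaf degenerates consistently to `|A| × 1`.
Edges are counted, not weight-summed, by default (`weighted=True` sums
leaf-edge weights instead, meaningful when those weights live in [0, 1]).

Diverging coloring is linear in each half-domain around the midpoint
(default domain ±max|value| about 0), with a blue–white–red palette —
the print rendering of up/down regulation is a style choice, not a
contract.  Inverse sizing maps the minimum distance to the maximum size
linearly; constant input maps to the midrange size to avoid a degenerate
scale.

## Nested force-directed layout

The embedder is in the Fruchterman–Reingold family: spring attraction
`d²/k` along edges, pairwise repulsion `C·k²/d` (with `k = rest_length`,
`C = repulsion`), synchronous updates, per-node displacement capped by a
temperature that decays geometrically (`cooling`, default 0.97) each
iteration.  Three adaptations give level decoupling:

1. forces act only between *siblings* — nodes sharing a parent, with
   containers acting as super-nodes at their own level;
2. an edge whose endpoints lie in different containers applies its spring
   force to the two *representatives* (the ancestors that are children of
   the deepest common container), never to hidden members;
3. a member whose distance from its container center exceeds
   0.75 × the container radius feels a linear restoring force
   (`containment_stiffness`, default 4.0, per unit of overshoot).

Container centers are recomputed each iteration as the centroid of their
children, and the container radius is
`container_padding × sqrt(leaf count) × rest_length / 2` (area
proportional to membership, default padding 1.8, minimum radius
`rest_length/2`).  A container's net displacement translates all its
descendants rigidly; the cap applies to each leaf's total displacement,
so the maximum displacement per step never exceeds the temperature.  All
forces depend only on relative positions, hence the layout is
translation-equivariant, and the only randomness is the seeded uniform
initial placement in a square of side `2·sqrt(n)·rest_length` — identical
(graph, params) pairs produce bit-identical layouts.

For an isolated connected pair the force balance `d²/k = C·k²/d` gives
the closed-form equilibrium `d* = k·C^(1/3)`, which the tests check to
5%.  The stiffness/padding defaults were chosen so that sibling repulsion
inside a container equilibrates safely inside the containment radius;
they are qualitative constants of the embedder, not fitted quantities.
Convergence is declared when the maximum displacement drops below `tol`
(default 1e-3) and reported, not raised, if `max_iter` (default 500) is
hit first.  Static circle/grid layouts are provided as trivial helpers
outside the force model.

## Synthetic-data generators

All generators are pure functions of their spec, seed included.

- **Modular toy graph** (`m=5`, `nmax=30` by default): ids split
  near-evenly into `m` planted modules (stored as a node attribute, not
  as containers — discovering the modules is the pipeline's job), each
  intra-module pair wired with `p_in=0.3`, inter-module with
  `p_out=0.01`.  These probabilities are the package's own choice, set so
  the modules are statistically separable at 30 nodes while leaving a
  few cross edges for the aggregation layer to summarize.
- **Scale-free graph**: the step model — a single vertex and no edge
  first, then one vertex per step attached to an existing vertex with
  probability proportional to degree + 1 (the +1 bootstraps the
  degree-zero start), giving exactly n−1 edges and a connected graph for
  every n and seed, with a right-skewed degree distribution.
- **Expression matrix**: each module has a latent per-sample profile;
  gene rows are `effect × latent + noise × N(0,1)` (defaults: 20
  samples, effect 3, noise 1 — within-module correlations ≈ 0.9, between
  ≈ 0), plus per-gene log2 fold-changes (module mean + scatter) and
  binding-site distances drawn exponentially with mean 50 kb, emulating
  the empirical pattern that most transcription-factor binding sites are
  distal to their targets.
- **Time course** (defaults: 200-node interactome, timepoints 3/6/12 h,
  set sizes 10/20/40, `nested_fraction=0.8`): the DE set at t+1 keeps
  each gene of the set at t with probability `nested_fraction`, then tops
  up to its target size.  Each top-up gene is drawn from the *frontier*
  (non-member interaction partners of the current set) with probability
  `locality` (default 1.0), else uniformly from non-members.  The
  locality mechanism encodes that a transcriptional response propagates
  through the interaction neighbourhood of the responding genes; it is
  what makes the per-timepoint subnetworks connected, growing objects.
  At `locality=1` and `nested_fraction=1` every DE set is connected and
  nested, so the largest components form a strictly nested chain — the
  regime the time-course workflow's chain contract is stated in.  At
  `locality=0` the top-up is a plain uniform draw, where consecutive-set
  overlap follows the hypergeometric expectation.

What the generators deliberately do not emulate: measurement-level
artefacts (probe effects, normalization bias), realistic interactome
density and clustering (the step-model graph is a tree), hub-biased DE
calling, or correlated fold-changes across timepoints.  Tests passing on
these data show the machinery is correct under its stated model, not
that any biological conclusion transfers to a real dataset.

## Workflows

The co-expression pipeline thresholds |Pearson r| between expression
rows (absolute correlation with a hard threshold is the simplest faithful
rule; the threshold is exposed), drops zero-variance genes with a
warning, superimposes the complete-linkage dendrogram of the same rows
via `nest_dendrogram`, aggregates module edges over the outermost
containers and writes them back as association edges, and styles nodes
by `logfc` (diverging) and `kb_dist` (inverse size).  `module_recovery`
scores a result by majority vote: each container is labelled with the
most common planted module among its genes, and a gene counts as
recovered when its container's label is its own (unclustered genes count
against).

The time-course pipeline takes per-timepoint DE gene sets, keeps the
largest connected component L(t) of each, and chains containers: the
container of t is nested inside that of t+1 exactly when L(t) ⊆ L(t+1);
otherwise the two sit side by side with an association edge weighted by
`overlap / min(|L(t)|, |L(t+1)|)`.  Since a node has one parent, a gene
appearing in several non-nested components stays with its earliest
timepoint, and nodes are colored by that timepoint's fold-change.  Strict
set containment was chosen as the nesting rule because it is the only
unambiguous, testable reading of "earlier subnetworks nest into later
ones"; partial overlap is reported in the overlap table rather than
forced into the hierarchy.

## Numerical and I/O choices

Distances use scipy's `pdist`; merge heights are exact maxima of those
values, so oracle comparisons hold to 1e-9.  GraphML uses the nested
graph-in-node compound dialect (arbitrary depth survives a round trip;
readable by common tools), with one typed key per attribute name and
`repr` float serialization for losslessness.  JSON dumps nodes and edges
directly and re-adds parents topologically on read.  Edge-list import is
undirected regardless of row orientation; conflicting duplicate weights
keep the last value and warn.  The SVG exporter flips the y axis
(Cartesian layout coordinates vs. screen-down SVG) and formats
coordinates to two decimals, sorted deterministically, so identical
inputs produce identical bytes.

## Problem sizes used in the checks

The shipped verification runs use graphs of up to 50 nodes for
structural oracles (500 randomized operation sequences), matrices up to
12 rows against the O(n³) clustering oracle (100 draws), 200
planted-partition graphs for aggregation, 20 seeded nested fixtures for
the layout containment statistic, n up to 1000 for the scale-free
contract, 20 seeds × 30 genes for pipeline recovery, and 100 random
nested graphs for round-trip fidelity.  These sizes were picked to give
stable statistics while keeping the whole suite interactive-fast.

## Known limitations

- Only complete linkage and Euclidean distances are implemented; the cut
  metrics are integer root depth and a height threshold.
- The association layer is a flag on edges, not a second edge store;
  re-assigning an edge between layers beyond the automatic inference is
  not modelled.
- The layout is 2-D, O(siblings²) per level per iteration, and has no
  Barnes–Hut acceleration; it is meant for module-level pictures, not
  10⁵-node hairballs.
- `threshold_for_k` cannot guarantee exactly k clusters under tied merge
  heights.
- Statistical significance of inter-module connectivity is out of scope;
  the module edge weight is a descriptive density.
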