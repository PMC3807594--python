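# Methods

## Data model

Trees are stored rooted (nested nodes with ordered children, optional
branch length to the parent, optional support value on internal edges);
unrooted semantics are realized by the operations. A tree is *canonical*
when no node has a single child and the root is not bifurcating;
`suppress_unary` establishes this by contracting degree-2 chains and
dissolving a bifurcating root into its children's join, summing the merged
branch lengths. A missing branch length is `None`, never 0: a sum
involving a missing segment is missing, and a missing length never
satisfies a length threshold. Negative input lengths (rare tree-builder
artifacts) are clamped to zero with a warning rather than rejected.

All bipartition work happens over a `TaxonIndex`, the lexicographically
sorted taxon list; splits are Python-integer bitsets with bit *i* for
taxon *i*, stored in canonical orientation (bit 0 clear, complementing
otherwise) so split-set equality is plain set equality. Splits with a side
of size 1 or n−1 are trivial and excluded everywhere.

## Normal form

Normalization maps every rooted representation of an unrooted topology to
one rooted, child-ordered tree:

1. **Weights.** The weight of a subtree is its total node count (internal
   nodes plus leaves).
2. **Root.** The root is the node minimizing the maximum weight of any
   child subtree under that rooting ("most balanced by weight"). Computing
   each node's worst component takes one downward size pass plus the
   complement (total nodes − subtree size) for the parent side, so scoring
   all candidates is linear.
3. **Child order.** At every node, children sort by descending weight;
   ties break on the subtree's leaf-set bitset compared as an integer.
   Sibling leaf sets are disjoint and nonempty, so this order is total.
4. **Residual ties.** When several nodes are equally balanced, each
   candidate's fully sorted topology is serialized (leaves as taxon
   positions, children in sorted order) and the lexicographically smallest
   serialization wins. This subsumes comparing the candidates' child
   labels and makes the result a function of the unrooted topology alone —
   invariance under re-rooting and child permutation holds by
   construction, and the test suite verifies it by brute force over all
   rootings.

The serialization string doubles as the bin key and defines the total
order over normal forms. Binning inserts each tree's key into an ordered
map; bins are reported by descending size, ties by key, so output is
independent of input order. Interior labels are computed eagerly; lazy
evaluation is a constant-factor optimization, not a semantic requirement
at the forest sizes this implementation targets.

A bin's representative tree re-roots every member into normal-form shape
(edge lengths and supports follow their edges through the re-rooting) and
averages corresponding branch lengths arithmetically. Missing lengths are
excluded from each mean; an edge missing in all members stays missing.
Supports are averaged the same way.

## Robinson–Foulds distances

`rf_pair` is the full symmetric-difference count `|S(a) Δ S(b)|`; on
binary trees over one taxon set it is even and bounded by 2(n−3). Pairs
with fewer than 3 taxa have no nontrivial split and are at distance 0 by
definition. The all-pairs matrix inserts every tree's splits into one
global occurrence map — keyed by the exact canonical bitset, so there is
no lossy hashing and collisions are impossible — then accumulates shared
counts through the occurrence incidence matrix (one integer matrix
product) and applies `d = |S(i)| + |S(j)| − 2 s(i,j)`. The naive pairwise
computation is retained as the independent oracle in tests, alongside a
cross-check against dendropy's symmetric difference.

Some tools count only one side of the difference; `halved` converts a
matrix to that convention as `ceil(d/2)` per entry (exact division for
binary same-taxa trees, rounding half up where multifurcations make the
count odd). The full count is the default; the halved convention exists so
thresholds expressed in one-sided units (where odd edit distances are
meaningful) can be reproduced.

**Tolerant mode** compares trees with unequal taxon sets pairwise: each
pair is pruned to its taxon intersection (pairwise, not the global
intersection across the forest — so distances are over varying taxon
counts, which the user should keep in mind when choosing thresholds) and
compared over a pair-local index. Pairs sharing fewer than 3 taxa get a
missing entry and are reported; clustering refuses missing entries unless
a fill value is supplied (`--tolerant-fill`).

## Preprocessing

*Length collapse* contracts internal edges with length strictly below the
threshold; the children re-attach to the parent with their own lengths
(the sub-threshold edge length is discarded). Keeping children's lengths
unchanged is what makes the filter idempotent and compositional
(collapsing at a then b equals collapsing at max(a, b)); it operates on
the canonicalized tree so a bifurcating root's two edges are judged as
the single underlying central edge. Leaf edges are never contracted —
removing taxa is pruning's job — and missing lengths never collapse.

*Support collapse* dissolves internal nodes with support strictly below
the threshold, re-attaching children at child length + dissolved length,
which preserves every leaf's path length to the root. Nodes without a
support value are kept. When both filters are requested, support collapse
runs first: it changes lengths by summation, and the length filter should
judge final lengths.

Both thresholds are strict (`<`): an edge or node exactly at the threshold
survives.

*Pruning* removes leaves outside the keep set; a parent left with one
child is suppressed with lengths summed (the distance from the ancestor to
the surviving subtree is retained), while a polytomy parent keeps its
remaining children untouched.

## Clustering

Agglomeration is the standard scheme with Lance–Williams updates: single
= minimum, complete = maximum, UPGMA = size-weighted arithmetic mean
(default, matching common practice for averaging tree distances). When
several pairs tie at the minimal linkage distance, the pair whose
(smaller, larger) representative-label pair is lexicographically least
merges first — every run is bit-reproducible across platforms. The
implementation is quadratic per merge, ample for the forest sizes
involved; scipy's implementation serves as an independent oracle on
tie-free matrices in the tests.

Flat clusters cut the dendrogram into maximal subtrees whose internal
merge heights are all ≤ the threshold. Because merge heights are
non-decreasing toward the root for these linkages, a cut at 0 returns
exactly the zero-distance groups, i.e. the identical-topology bins, and
raising the threshold only ever merges clusters (the cluster count is
monotone non-increasing).

Per-cluster outputs: the **strict consensus** (the tree realizing the
intersection of the members' split sets — the intersection is laminar
because it is contained in any one member's split set, so the tree always
exists), and a representative **average tree** of the largest
identical-topology subgroup. Majority-rule consensus is a possible
extension, not currently implemented. The dendrogram exports to Newick
with each child's branch length equal to parent merge height minus child
height (an ultrametric rendering, path lengths proportional to linkage
distance) and to GraphViz DOT.

## Synthetic forests

The generator emulates a genome-wide ortholog tree set over a shared
panel: defaults are 10 taxa (a within-genus bacterial comparison), three
planted topologies at multiplicities 5/3/2 with pairwise RF ≥ 4, and
log-normal branch lengths with log-mean −3 and log-sd 1 (median length
0.05 substitutions/site — the scale of single-gene trees from closely
related strains). Each copy of a planted topology receives fresh lengths,
a random rooting, shuffled child orders and uniform-integer bootstrap
values in 60–100. Topologies come from sequential random leaf attachment,
which is deterministic per seed and covers topology space but is not the
uniform distribution over topologies; exhaustive enumeration (3, 15, 105
topologies at n = 4, 5, 6) backs the soundness/completeness tests.

With `short_branch_rate > 0`, a fixed subset of each base topology's
internal edges is designated short; every copy draws those lengths below
`short_branch_eps` (default 10⁻³) and may be NNI-flipped across a short
edge. This models estimation noise on poorly resolved branches: the
copies land in different bins, and a length collapse at any threshold
above ε merges them back into one bin per planted topology. With
`missing_taxa_rate > 0`, leaves are dropped per tree (at least 3 kept)
for tolerant-mode testing.

What the generator does *not* emulate: sequence-level estimation error
(no alignments are simulated), coalescent or duplication/loss processes,
rogue-taxon instability, and correlated support/length noise. Passing
tests therefore demonstrate the combinatorial machinery — normalization,
distances, clustering, collapse semantics — not the statistical behavior
of any tree-inference method on real data.

## Problem sizes and numerics

The test and acceptance runs use exhaustive enumeration at n ≤ 6, random
trees at n ≤ 12 taxa and forests of ≤ 30 trees, and hundreds of repeated
draws per property — sizes at which brute-force oracles (all rootings,
all pairs, graph components) stay exact and the whole suite runs in
seconds. Distances and merge heights below are exact integers or exact
dyadic/rational means; no floating-point tolerance is needed anywhere
except branch-length averaging, which uses plain double arithmetic.

Known limitations: no NEXUS/PhyloXML input, no reticulated networks, no
weighted/branch-score or quartet distances, no majority-rule consensus,
and no attempt at performance parity with specialized C implementations
of the RF matrix — clarity and exact reproducibility are the priorities
at the forest sizes this package targets.
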