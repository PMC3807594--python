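"""Agglomerative hierarchical clustering of trees from the RF matrix,
flat-cluster extraction at an edit-distance threshold, strict consensus
trees, and dendrogram ("tree of trees") export.

The agglomeration is the textbook scheme with Lance–Williams updates
(single = minimum, complete = maximum, UPGMA = size-weighted arithmetic
mean of inter-cluster distances).  It is implemented here rather than
delegated so the tie-break is fully specified: when several pairs attain
the minimal linkage distance, the pair whose (smaller representative
label, larger representative label) is lexicographically least merges
first, making every run deterministic across platforms.  Tests
cross-check the heights against scipy on tie-free matrices.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional

import numpy as np

from .newick_io import write_newick
from .rf import DistanceMatrix
from .tree_core import Node, PhyloTree, TaxonIndex, orient, popcount

LINKAGE_METHODS = ("single", "complete", "upgma")


@dataclass
class DendroNode:
    """Node of the binary merge tree; leaves carry tree names, internal
    nodes the merge height (linkage distance)."""

    height: float = 0.0
    name: Optional[str] = None
    children: list["DendroNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaf_names(self) -> list[str]:
        if self.is_leaf:
            return [self.name]
        out: list[str] = []
        for c in self.children:
            out.extend(c.leaf_names())
        return out


@dataclass
class Dendrogram:
    root: DendroNode
    method: str

    def leaves(self) -> list[str]:
        return self.root.leaf_names()

    def iter_nodes(self) -> Iterator[DendroNode]:
        stack = [self.root]
        while stack:
            nd = stack.pop()
            yield nd
            stack.extend(reversed(nd.children))


def linkage(d: DistanceMatrix, method: str = "upgma") -> Dendrogram:
    """Agglomerative clustering of the distance matrix.

    ``method`` is one of ``single``, ``complete``, ``upgma``.  Missing
    entries (incomparable tolerant-mode pairs) are an error; fill them
    first with a ``--tolerant-fill`` policy
    (:meth:`DistanceMatrix.fill_missing`).
    """
    if method not in LINKAGE_METHODS:
        raise ValueError(f"unknown linkage method {method!r}; use one of {LINKAGE_METHODS}")
    if d.has_missing():
        raise ValueError(
            "distance matrix has missing entries (incomparable pairs); "
            "apply a --tolerant-fill policy before clustering"
        )
    n = d.n
    if n == 0:
        raise ValueError("empty distance matrix")
    nodes: list[Optional[DendroNode]] = [
        DendroNode(height=0.0, name=lbl) for lbl in d.labels
    ]
    reps: list[Optional[str]] = list(d.labels)  # lexicographically smallest member
    sizes = np.ones(n, dtype=np.int64)
    active = np.ones(n, dtype=bool)
    dist = d.data.astype(float).copy()
    np.fill_diagonal(dist, np.inf)
    dist[:, ~active] = np.inf

    for _ in range(n - 1):
        masked = np.where(active[:, None] & active[None, :], dist, np.inf)
        current_min = masked.min()
        ii, jj = np.where(masked == current_min)
        # deterministic tie-break: lexicographically least (small rep, big rep)
        best = None
        best_pair = None
        for i, j in zip(ii.tolist(), jj.tolist()):
            if i >= j:
                continue
            key = tuple(sorted((reps[i], reps[j])))
            if best is None or key < best:
                best, best_pair = key, (i, j)
        assert best_pair is not None
        i, j = best_pair
        merged = DendroNode(height=float(current_min), children=[nodes[i], nodes[j]])
        # Lance-Williams update of cluster i; retire cluster j
        di, dj = dist[i], dist[j]
        if method == "single":
            new_row = np.minimum(di, dj)
        elif method == "complete":
            new_row = np.maximum(di, dj)
        else:  # upgma: size-weighted arithmetic mean
            new_row = (sizes[i] * di + sizes[j] * dj) / (sizes[i] + sizes[j])
        dist[i, :] = new_row
        dist[:, i] = new_row
        dist[i, i] = np.inf
        active[j] = False
        sizes[i] += sizes[j]
        nodes[i] = merged
        reps[i] = min(reps[i], reps[j])
        nodes[j] = None
        reps[j] = None

    root = nodes[int(np.flatnonzero(active)[0])]
    assert root is not None
    return Dendrogram(root=root, method=method)


# ---------------------------------------------------------------------------
# flat clusters
# ---------------------------------------------------------------------------

@dataclass
class Clustering:
    """Partition of tree names into clusters, largest first."""

    clusters: list[list[str]]
    threshold: float

    def __post_init__(self) -> None:
        self.clusters = sorted(
            (sorted(c) for c in self.clusters), key=lambda c: (-len(c), c[0])
        )

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    @property
    def n_singletons(self) -> int:
        return sum(1 for c in self.clusters if len(c) == 1)

    def sizes(self) -> list[int]:
        return [len(c) for c in self.clusters]

    def as_sets(self) -> set[frozenset[str]]:
        return {frozenset(c) for c in self.clusters}


def flat_clusters(dend: Dendrogram, threshold: float) -> Clustering:
    """Cut the dendrogram at an edit-distance threshold.

    Clusters are the maximal subtrees all of whose internal merge heights
    are at most ``threshold``; threshold 0 therefore yields exactly the
    identical-topology bins (zero-distance groups).
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    clusters: list[list[str]] = []

    def cut(nd: DendroNode) -> None:
        # merge heights are non-decreasing toward the root, so a subtree
        # whose root merges at <= threshold is entirely within threshold
        if nd.is_leaf or nd.height <= threshold:
            clusters.append(nd.leaf_names())
        else:
            for c in nd.children:
                cut(c)

    cut(dend.root)
    return Clustering(clusters=clusters, threshold=threshold)


# ---------------------------------------------------------------------------
# consensus
# ---------------------------------------------------------------------------

def strict_consensus(trees: list[PhyloTree], index: TaxonIndex) -> PhyloTree:
    """Strict consensus: the tree whose split set is the intersection of
    the members' split sets.  No branch lengths; all trees must share one
    taxon set."""
    from .tree_core import bipartitions_of  # local import to avoid cycle noise

    if not trees:
        raise ValueError("no trees to form a consensus of")
    taxon_sets = {t.taxa() for t in trees}
    if len(taxon_sets) > 1:
        raise ValueError("heterogeneous taxon sets; consensus undefined")
    (taxa,) = taxon_sets
    common = bipartitions_of(trees[0], index)
    for t in trees[1:]:
        common = common & bipartitions_of(t, index)
    return tree_from_splits(common, taxa, index)


def tree_from_splits(
    splits: frozenset[int] | set[int], taxa: frozenset[str], index: TaxonIndex
) -> PhyloTree:
    """Build the (multifurcating) tree realizing a compatible split set.

    Splits are canonical bitsets over ``index``; the side not containing
    the position-0 taxon is treated as a clade and clades are nested into
    a star over ``taxa``.  The split set must be pairwise compatible
    (always true for an intersection of one tree's splits)."""
    positions = sorted(index.position(t) for t in taxa)
    root = Node()
    node_bits: dict[int, int] = {}
    for pos in positions:
        leaf = Node(label=index.name_at(pos))
        node_bits[id(leaf)] = 1 << pos
        root.add(leaf)
    node_bits[id(root)] = sum(1 << p for p in positions)
    # insert larger clades first so smaller ones nest inside them
    for bits in sorted(splits, key=popcount, reverse=True):
        clade = orient(bits, index)
        if clade & ~node_bits[id(root)]:
            raise ValueError("split references taxa outside the consensus set")
        # descend to the smallest existing node containing the clade
        host = root
        descended = True
        while descended:
            descended = False
            for c in host.children:
                cb = node_bits[id(c)]
                if clade & cb == clade and popcount(cb) > popcount(clade):
                    host = c
                    descended = True
                    break
        inside = [c for c in host.children if node_bits[id(c)] & clade]
        covered = 0
        for c in inside:
            if node_bits[id(c)] & ~clade:
                raise ValueError("incompatible split set")
            covered |= node_bits[id(c)]
        if covered != clade:
            raise ValueError("incompatible split set")
        if len(inside) == len(host.children):
            continue  # clade already equals the host node
        new = Node(children=inside)
        node_bits[id(new)] = clade
        host.children = [c for c in host.children if c not in inside] + [new]
    return PhyloTree(root)


# ---------------------------------------------------------------------------
# cluster summaries
# ---------------------------------------------------------------------------

@dataclass
class ClusterSummary:
    members: list[str]
    consensus: PhyloTree
    representative: PhyloTree  # branch-length average of the largest identical-topology subgroup

    @property
    def size(self) -> int:
        return len(self.members)


def summarize_clusters(
    clustering: Clustering,
    trees_by_name: dict[str, PhyloTree],
    index: TaxonIndex,
) -> list[ClusterSummary]:
    """Per-cluster strict consensus plus a branch-length-averaged
    representative of the largest identical-topology subgroup."""
    from .newick_io import ForestEntry, RawForest
    from .normalform import bin_trees

    out: list[ClusterSummary] = []
    for members in clustering.clusters:
        member_trees = [trees_by_name[m] for m in members]
        cons = strict_consensus(member_trees, index)
        sub = RawForest([ForestEntry(name=m, tree=trees_by_name[m]) for m in members])
        table = bin_trees(sub, index)
        out.append(
            ClusterSummary(
                members=list(members),
                consensus=cons,
                representative=table.bins()[0].representative(),
            )
        )
    return out


# ---------------------------------------------------------------------------
# dendrogram export
# ---------------------------------------------------------------------------

def dendrogram_to_newick(dend: Dendrogram) -> str:
    """Ultrametric Newick rendering of the tree of trees: each child's
    branch length is its parent's merge height minus its own height
    (leaves sit at height 0), so path lengths are proportional to linkage
    distance."""

    def convert(nd: DendroNode) -> Node:
        if nd.is_leaf:
            return Node(label=nd.name)
        out = Node()
        for c in nd.children:
            cc = convert(c)
            cc.length = nd.height - c.height
            out.add(cc)
        return out

    return write_newick(PhyloTree(convert(dend.root)), include_support=False)


def dendrogram_to_dot(dend: Dendrogram, graph_name: str = "tree_of_trees") -> str:
    """GraphViz DOT rendering of the tree of trees (text output; render
    with any DOT viewer)."""
    lines = [f"graph {graph_name} {{", "  node [shape=oval];"]
    counter = 0

    def visit(nd: DendroNode) -> str:
        nonlocal counter
        my_id = f"n{counter}"
        counter += 1
        if nd.is_leaf:
            lines.append(f'  {my_id} [label="{nd.name}"];')
        else:
            lines.append(f'  {my_id} [label="h={nd.height:g}", shape=point];')
            for c in nd.children:
                child_id = visit(c)
                lines.append(f"  {my_id} -- {child_id} [len={nd.height - c.height:g}];")
        return my_id

    visit(dend.root)
    lines.append("}")
    return "\n".join(lines) + "\n"
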