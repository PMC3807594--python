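"""Noise reduction and taxon-set reconciliation applied before
binning/clustering.

Two collapse filters address noise in trees built from closely related
taxa: a branch-length threshold (internal edges shorter than the
threshold are contracted, inserting a polytomy in their place) and a
bootstrap-support threshold (poorly supported internal nodes are
dissolved, with the branch lengths from their children added to the
dissolved edge so root-to-leaf path lengths are preserved).  Both use
strict inequality: an edge exactly at the threshold survives.

Pruning restricts trees to a taxon subset.  Removing a leaf from a
polytomy leaves the parent and remaining sisters unchanged; removing it
from a binary node suppresses the now-unary parent, summing the two
branch lengths so the distance from the grandparent to the surviving
subtree is retained.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .tree_core import Node, PhyloTree, _combine_lengths, suppress_unary


class IncomparableTreesError(ValueError):
    """A pair of trees shares too few taxa for any nontrivial split."""


@dataclass(frozen=True)
class CollapseSpec:
    """Which collapse filters to apply.

    At least one criterion must be set when a collapse is requested.  When
    both are given, the support collapse runs first (it changes branch
    lengths by summation), then the length collapse sees the final
    lengths.
    """

    min_branch_len: Optional[float] = None
    min_support: Optional[float] = None

    def __post_init__(self) -> None:
        if self.min_branch_len is None and self.min_support is None:
            raise ValueError("CollapseSpec: at least one criterion must be set")

    def apply(self, tree: PhyloTree) -> PhyloTree:
        out = tree
        if self.min_support is not None:
            out = collapse_low_support(out, self.min_support)
        if self.min_branch_len is not None:
            out = collapse_short_branches(out, self.min_branch_len)
        return out


def collapse_short_branches(tree: PhyloTree, threshold: float) -> PhyloTree:
    """Contract every internal edge with length strictly below ``threshold``.

    The children of a contracted node re-attach to its parent with their
    own lengths, forming a polytomy.  Leaf edges are never contracted
    (that would delete a taxon — pruning's job), and edges with a missing
    length are never contracted.  The result is canonical.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    # canonicalize first: the filter must see the unrooted topology's edges
    # (a bifurcating root's two edges are one underlying central edge)
    root = suppress_unary(tree).root

    def walk(nd: Node, is_root: bool) -> list[Node]:
        # returns the node(s) that should take nd's place under its parent
        new_children: list[Node] = []
        for c in nd.children:
            new_children.extend(walk(c, False))
        nd.children = new_children
        if (
            not is_root
            and not nd.is_leaf
            and nd.length is not None
            and nd.length < threshold
        ):
            return nd.children
        return [nd]

    walk(root, True)
    return suppress_unary(PhyloTree(root))


def collapse_low_support(tree: PhyloTree, threshold: float) -> PhyloTree:
    """Dissolve every internal node whose support is strictly below
    ``threshold``.

    The children of a dissolved node re-attach to its parent with branch
    length ``child length + dissolved node's length`` (missing absorbs),
    so each leaf's path length to the root is preserved.  Nodes without a
    support value are kept.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    root = suppress_unary(tree).root

    def walk(nd: Node, is_root: bool) -> list[Node]:
        new_children: list[Node] = []
        for c in nd.children:
            new_children.extend(walk(c, False))
        nd.children = new_children
        if (
            not is_root
            and not nd.is_leaf
            and nd.support is not None
            and nd.support < threshold
        ):
            for c in nd.children:
                c.length = _combine_lengths(c.length, nd.length)
            return nd.children
        return [nd]

    walk(root, True)
    return suppress_unary(PhyloTree(root))


def prune_taxa(tree: PhyloTree, keep: set[str]) -> PhyloTree:
    """Remove all leaves whose label is not in ``keep``.

    A parent left with a single child is suppressed with the two branch
    lengths summed; a parent in a polytomy keeps its remaining children
    unchanged.  Fewer than 2 surviving taxa is an error.
    """
    surviving = tree.taxa() & set(keep)
    if len(surviving) < 2:
        raise IncomparableTreesError(
            f"pruning would leave {len(surviving)} taxa; need at least 2"
        )
    root = tree.root.copy()

    def walk(nd: Node) -> Optional[Node]:
        if nd.is_leaf:
            return nd if nd.label in keep else None
        new_children = []
        for c in nd.children:
            kept = walk(c)
            if kept is not None:
                new_children.append(kept)
        nd.children = new_children
        if not nd.children:
            return None
        return nd

    root = walk(root)
    assert root is not None
    return suppress_unary(PhyloTree(root))


def restrict_to_common(
    tree_a: PhyloTree, tree_b: PhyloTree
) -> tuple[PhyloTree, PhyloTree]:
    """Prune both trees to their common taxon set.

    Below 3 shared taxa no nontrivial split exists and the pair is
    incomparable."""
    common = tree_a.taxa() & tree_b.taxa()
    if len(common) < 3:
        raise IncomparableTreesError(
            f"trees share only {len(common)} taxa; need at least 3"
        )
    return prune_taxa(tree_a, common), prune_taxa(tree_b, common)
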