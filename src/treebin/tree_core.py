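"""Core tree and bipartition machinery shared by all analysis stages.

Trees are stored *rooted* as nested :class:`Node` objects; unrooted
semantics (bipartitions, re-rooting, normal forms) are realized by the
operations in this module and in :mod:`treebin.normalform`.  A tree is
*canonical* when no node has exactly one child and the root is not
bifurcating — i.e. the rooted representation is a faithful encoding of an
unrooted multifurcating topology.

Bipartitions (splits) are encoded as Python integers used as fixed-width
bitsets over a :class:`TaxonIndex`: bit ``i`` corresponds to the taxon at
position ``i`` of the lexicographically sorted taxon list.  A split is
stored in canonical orientation — the side *not* containing the taxon at
position 0 — so split-set equality is plain set equality.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Iterator, Optional


class Node:
    """A node of a rooted phylogenetic tree.

    Attributes
    ----------
    label : str or None
        Leaf label (taxon name).  Internal nodes normally have ``None``.
    length : float or None
        Branch length of the edge to the parent; ``None`` means the length
        is *missing* (unknown), which is distinct from 0.0.
    support : float or None
        Support value (e.g. bootstrap) attached to the edge above this
        node; meaningful for internal nodes only.
    children : list of Node
        Ordered child list; empty for leaves.
    """

    __slots__ = ("label", "length", "support", "children")

    def __init__(
        self,
        label: Optional[str] = None,
        length: Optional[float] = None,
        support: Optional[float] = None,
        children: Optional[Iterable["Node"]] = None,
    ) -> None:
        self.label = label
        self.length = length
        self.support = support
        self.children: list[Node] = list(children) if children is not None else []

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def add(self, child: "Node") -> None:
        self.children.append(child)

    def copy(self) -> "Node":
        return Node(
            self.label,
            self.length,
            self.support,
            [c.copy() for c in self.children],
        )

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        if self.is_leaf:
            return f"Leaf({self.label!r})"
        return f"Node({len(self.children)} children)"


class PhyloTree:
    """A rooted multi-way tree with leaf labels, optional branch lengths
    and optional internal support values."""

    __slots__ = ("root",)

    def __init__(self, root: Node) -> None:
        self.root = root

    # -- traversal ----------------------------------------------------
    def iter_nodes(self) -> Iterator[Node]:
        """Preorder traversal."""
        stack = [self.root]
        while stack:
            nd = stack.pop()
            yield nd
            stack.extend(reversed(nd.children))

    def leaves(self) -> list[Node]:
        return [nd for nd in self.iter_nodes() if nd.is_leaf]

    def leaf_labels(self) -> list[str]:
        return [nd.label for nd in self.leaves()]

    def taxa(self) -> frozenset[str]:
        return frozenset(self.leaf_labels())

    @property
    def n_leaves(self) -> int:
        return sum(1 for nd in self.iter_nodes() if nd.is_leaf)

    def copy(self) -> "PhyloTree":
        return PhyloTree(self.root.copy())

    def validate(self) -> None:
        """Raise ``ValueError`` on duplicate or missing leaf labels."""
        seen: set[str] = set()
        for nd in self.iter_nodes():
            if nd.is_leaf:
                if nd.label is None:
                    raise ValueError("leaf without a label")
                if nd.label in seen:
                    raise ValueError(f"duplicate leaf label {nd.label!r}")
                seen.add(nd.label)

    def __repr__(self) -> str:  # pragma: no cover
        return f"PhyloTree({self.n_leaves} leaves)"


class TaxonIndex:
    """Immutable bidirectional map taxon-name <-> integer position.

    Names are sorted lexicographically; the position of a name defines its
    bit in every bipartition bitset built over this index.
    """

    __slots__ = ("names", "_pos")

    def __init__(self, names: Iterable[str]) -> None:
        ordered = sorted(set(names))
        self.names: tuple[str, ...] = tuple(ordered)
        self._pos = {name: i for i, name in enumerate(self.names)}
        if not self.names:
            raise ValueError("empty taxon index")

    @classmethod
    def from_trees(cls, trees: Iterable[PhyloTree]) -> "TaxonIndex":
        names: set[str] = set()
        for t in trees:
            names.update(t.leaf_labels())
        return cls(names)

    def __len__(self) -> int:
        return len(self.names)

    def __contains__(self, name: str) -> bool:
        return name in self._pos

    def __eq__(self, other: object) -> bool:
        return isinstance(other, TaxonIndex) and self.names == other.names

    def __hash__(self) -> int:
        return hash(self.names)

    def position(self, name: str) -> int:
        try:
            return self._pos[name]
        except KeyError:
            raise KeyError(f"taxon {name!r} not in index") from None

    def name_at(self, pos: int) -> str:
        return self.names[pos]

    @property
    def full_mask(self) -> int:
        return (1 << len(self.names)) - 1

    def __repr__(self) -> str:  # pragma: no cover
        return f"TaxonIndex({len(self)} taxa)"


# ---------------------------------------------------------------------------
# bitset / bipartition helpers
# ---------------------------------------------------------------------------

def leaf_set(node: Node, index: TaxonIndex) -> int:
    """Bitset of the taxa at or below ``node`` (under the current rooting)."""
    bits = 0
    stack = [node]
    while stack:
        nd = stack.pop()
        if nd.is_leaf:
            bits |= 1 << index.position(nd.label)
        else:
            stack.extend(nd.children)
    return bits


def orient(bits: int, index: TaxonIndex) -> int:
    """Canonical orientation of a split: the bit of the lexicographically
    first taxon (position 0) is always clear."""
    if bits & 1:
        return index.full_mask ^ bits
    return bits


def popcount(bits: int) -> int:
    return bits.bit_count()


def bipartitions_of(tree: PhyloTree, index: TaxonIndex) -> frozenset[int]:
    """The set of nontrivial bipartitions (canonically oriented bitsets)
    induced by the unrooted topology of ``tree``.

    One bipartition per internal edge; splits with a side of size 1 or
    ``n - 1`` are trivial and excluded.  The result is invariant under the
    choice of rooting (a bifurcating root contributes its single underlying
    edge once).
    """
    n = len(index)
    taxa = tree.taxa()
    unknown = taxa - set(index.names)
    if unknown:
        raise KeyError(f"leaf labels not in taxon index: {sorted(unknown)}")
    splits: set[int] = set()

    def collect(nd: Node, is_root: bool) -> int:
        if nd.is_leaf:
            return 1 << index.position(nd.label)
        bits = 0
        for c in nd.children:
            bits |= collect(c, False)
        if not is_root:
            pc = popcount(bits)
            if 2 <= pc <= n - 2:
                splits.add(orient(bits, index))
        return bits

    collect(tree.root, True)
    return frozenset(splits)


# ---------------------------------------------------------------------------
# canonicalization (degree-2 suppression / derooting)
# ---------------------------------------------------------------------------

def _combine_lengths(a: Optional[float], b: Optional[float]) -> Optional[float]:
    # missing + x = missing: a chain with an unknown segment has unknown total
    if a is None or b is None:
        return None
    return a + b


def suppress_unary(tree: PhyloTree) -> PhyloTree:
    """Contract degree-2 chains and dissolve a bifurcating root.

    Merged branch lengths are summed (a missing length absorbs the sum).
    The input is not modified.  Two-leaf trees are returned as-is apart
    from chain contraction (they have no internal edge to dissolve).
    """
    root = tree.root.copy()

    def contract(nd: Node) -> Node:
        # collapse runs of single-child internal nodes below nd
        new_children = []
        for c in nd.children:
            c = contract(c)
            while len(c.children) == 1:
                only = c.children[0]
                only.length = _combine_lengths(c.length, only.length)
                if only.support is None:
                    only.support = c.support
                c = only
            new_children.append(c)
        nd.children = new_children
        return nd

    root = contract(root)
    while len(root.children) == 1:
        child = root.children[0]
        child.length = None
        child.support = None
        root = child
    if len(root.children) == 2:
        a, b = root.children
        internal = b if not b.is_leaf else (a if not a.is_leaf else None)
        if internal is not None:
            other = a if internal is b else b
            other.length = _combine_lengths(other.length, internal.length)
            if other.support is None:
                other.support = internal.support
            root = Node(children=[other] + internal.children)
    return PhyloTree(root)


# ---------------------------------------------------------------------------
# re-rooting (for normal forms and invariance checks)
# ---------------------------------------------------------------------------

def _adjacency(tree: PhyloTree):
    """Undirected view: node -> list of (neighbor, length, support).

    Edge length/support live on the child end in the rooted storage; the
    undirected edge carries them symmetrically.
    """
    adj: dict[int, list[tuple[Node, Optional[float], Optional[float]]]] = {}
    nodes: list[Node] = []

    def visit(nd: Node) -> None:
        nodes.append(nd)
        adj.setdefault(id(nd), [])
        for c in nd.children:
            adj[id(nd)].append((c, c.length, c.support))
            adj.setdefault(id(c), []).append((nd, c.length, c.support))
            visit(c)

    visit(tree.root)
    return nodes, adj


def reroot_at(tree: PhyloTree, target: Node) -> PhyloTree:
    """A new tree over the same unrooted topology, rooted at ``target``
    (a node object of ``tree``).  Edge lengths and supports follow their
    edges."""
    _, adj = _adjacency(tree)

    def build(nd: Node, parent: Optional[Node], length, support) -> Node:
        out = Node(nd.label, length, support)
        for nb, ln, sp in adj[id(nd)]:
            if nb is parent:
                continue
            out.add(build(nb, nd, ln, sp))
        return out

    return PhyloTree(build(target, None, None, None))


def internal_nodes(tree: PhyloTree) -> list[Node]:
    return [nd for nd in tree.iter_nodes() if not nd.is_leaf]


def all_rootings(tree: PhyloTree) -> Iterator[PhyloTree]:
    """The tree re-rooted at every internal node of its unrooted topology."""
    for nd in internal_nodes(tree):
        yield reroot_at(tree, nd)


def clamp_negative_lengths(tree: PhyloTree) -> PhyloTree:
    """Clamp negative branch lengths to zero, in place, with a warning.

    Some tree builders emit tiny negative lengths; topology analyses treat
    them as zero-length edges rather than failing.
    """
    clamped = 0
    for nd in tree.iter_nodes():
        if nd.length is not None and nd.length < 0:
            nd.length = 0.0
            clamped += 1
    if clamped:
        warnings.warn(
            f"clamped {clamped} negative branch length(s) to 0", stacklevel=2
        )
    return tree
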