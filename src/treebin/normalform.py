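"""Canonical normal form for leaf-labeled unrooted topologies, the total
order over normal forms, and exact-topology binning.

An input gene tree is a labeled, *unrooted*, *unordered* topology stored
in an arbitrary rooted representation.  Normalization maps every such
representation of one topology to a single rooted, child-ordered tree:

* **root choice** — the root is the node that is most balanced by
  *weight*, where the weight of a subtree is its total node count
  (internal nodes + leaves): the chosen root minimizes the maximum weight
  of any of its child subtrees;
* **child order** — at every node, children are sorted by descending
  weight, ties broken by the subtree's leaf-set label (the bitset of
  taxa below it, compared as an integer over the sorted taxon index);
* **residual root ties** — when several nodes are equally balanced, the
  candidate whose fully sorted serialization is lexicographically
  smallest wins.  This subsumes the children-label comparison and makes
  normalization a total function of the unrooted topology alone.

Two trees have equal normal forms iff they are the same unrooted
topology, so binning reduces to ordered-map insertion keyed by the
serialized normal form; branch lengths and supports never enter the key
but are carried alongside so a bin's representative *average tree* can be
computed by averaging corresponding branch lengths over the members.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .newick_io import RawForest
from .tree_core import (
    Node,
    PhyloTree,
    TaxonIndex,
    _adjacency,
    _combine_lengths,
    suppress_unary,
)


@dataclass(frozen=True)
class NormalForm:
    """A canonical rooted, child-ordered topology key.

    ``key`` is an injective serialization of the normalized topology
    (leaves appear as taxon positions); equality and the total order are
    string equality/ordering on it.
    """

    key: str
    index: TaxonIndex

    def __lt__(self, other: "NormalForm") -> bool:
        _check_same_index(self, other)
        return self.key < other.key

    def __le__(self, other: "NormalForm") -> bool:
        _check_same_index(self, other)
        return self.key <= other.key


def _check_same_index(a: NormalForm, b: NormalForm) -> None:
    if a.index != b.index:
        raise ValueError("cannot compare normal forms over different taxon indices")


def compare(a: NormalForm, b: NormalForm) -> int:
    """Total order over normal forms: -1, 0 or +1."""
    _check_same_index(a, b)
    if a.key < b.key:
        return -1
    if a.key > b.key:
        return 1
    return 0


def normalize(tree: PhyloTree, index: TaxonIndex) -> NormalForm:
    """The normal form of ``tree``'s unrooted topology.

    The output is identical for every rooting and child permutation of
    the same topology; branch lengths and supports are ignored.
    """
    nf, _ = _normalize_impl(tree, index)
    return nf


def normalized_tree(tree: PhyloTree, index: TaxonIndex) -> tuple[NormalForm, PhyloTree]:
    """Normal form plus a copy of the tree re-rooted and child-ordered
    into normal-form shape, with branch lengths and supports carried
    along their edges (used for branch-length averaging)."""
    return _normalize_impl(tree, index)


def _normalize_impl(tree: PhyloTree, index: TaxonIndex) -> tuple[NormalForm, PhyloTree]:
    t = suppress_unary(tree)
    for label in t.leaf_labels():
        if label not in index:
            raise KeyError(f"leaf label {label!r} not in taxon index")
    if t.root.is_leaf:
        # a forest may contain a 1-leaf "tree" only transiently; treat the
        # single leaf as its own root
        nf = NormalForm(key=f"L{index.position(t.root.label)}", index=index)
        return nf, t

    nodes, adj = _adjacency(t)
    n_nodes = len(nodes)

    # subtree node-counts under the stored rooting, then per-node maximum
    # component weight when that node is taken as root
    size: dict[int, int] = {}

    def sizes(nd: Node, parent: Optional[Node]) -> int:
        s = 1
        for nb, _, _ in adj[id(nd)]:
            if nb is parent:
                continue
            s += sizes(nb, nd)
        size[id(nd)] = s
        return s

    sizes(t.root, None)

    def max_component(nd: Node, parent: Optional[Node]) -> int:
        worst = 0
        for nb, _, _ in adj[id(nd)]:
            if nb is parent:
                comp = n_nodes - size[id(nd)]
            else:
                comp = size[id(nb)]
            worst = max(worst, comp)
        return worst

    parent_of: dict[int, Optional[Node]] = {id(t.root): None}

    def record_parents(nd: Node, parent: Optional[Node]) -> None:
        parent_of[id(nd)] = parent
        for nb, _, _ in adj[id(nd)]:
            if nb is not parent:
                record_parents(nb, nd)

    record_parents(t.root, None)

    candidates = [nd for nd in nodes if not nd.is_leaf]
    balances = {id(nd): max_component(nd, parent_of[id(nd)]) for nd in candidates}
    best_balance = min(balances.values())
    finalists = [nd for nd in candidates if balances[id(nd)] == best_balance]

    best_key: Optional[str] = None
    best_root: Optional[Node] = None
    for cand in finalists:
        key, rooted = _sorted_rooting(cand, adj, index)
        if best_key is None or key < best_key:
            best_key, best_root = key, rooted
    assert best_key is not None and best_root is not None
    return NormalForm(key=best_key, index=index), PhyloTree(best_root)


def _sorted_rooting(root: Node, adj, index: TaxonIndex) -> tuple[str, Node]:
    """Root the unrooted topology at ``root``, sort children everywhere by
    (descending weight, ascending leaf-set bitset), and serialize."""

    def build(nd: Node, parent: Optional[Node], length, support):
        if nd.is_leaf:
            pos = index.position(nd.label)
            out = Node(nd.label, length, support)
            return f"L{pos}", 1, 1 << pos, out
        entries = []
        for nb, ln, sp in adj[id(nd)]:
            if nb is parent:
                continue
            entries.append(build(nb, nd, ln, sp))
        entries.sort(key=lambda e: (-e[1], e[2]))
        key = "(" + ",".join(e[0] for e in entries) + ")"
        weight = 1 + sum(e[1] for e in entries)
        bits = 0
        for e in entries:
            bits |= e[2]
        out = Node(None, length, support, [e[3] for e in entries])
        return key, weight, bits, out

    key, _, _, rooted = build(root, None, None, None)
    return key, rooted


# ---------------------------------------------------------------------------
# binning
# ---------------------------------------------------------------------------

@dataclass
class Bin:
    """One equivalence class of exactly identical topologies."""

    normal_form: NormalForm
    members: list[tuple[str, PhyloTree]] = field(default_factory=list)

    @property
    def size(self) -> int:
        return len(self.members)

    def member_names(self) -> list[str]:
        return [name for name, _ in self.members]

    def representative(self) -> PhyloTree:
        """Average tree over the bin members (see :func:`average_tree`)."""
        return average_tree([t for _, t in self.members], self.normal_form.index)


class BinTable:
    """Ordered map normal form -> bin, reported by descending size.

    Keys are unique and total membership equals the number of input
    trees.  Iteration order: descending bin size, ties by the normal-form
    total order, so output is deterministic regardless of input order.
    """

    def __init__(self, index: TaxonIndex) -> None:
        self.index = index
        self._bins: dict[str, Bin] = {}

    def insert(self, nf: NormalForm, name: str, tree: PhyloTree) -> None:
        b = self._bins.get(nf.key)
        if b is None:
            b = Bin(normal_form=nf)
            self._bins[nf.key] = b
        b.members.append((name, tree))

    def bins(self) -> list[Bin]:
        return sorted(
            self._bins.values(), key=lambda b: (-b.size, b.normal_form.key)
        )

    def sizes(self) -> list[int]:
        return [b.size for b in self.bins()]

    @property
    def n_bins(self) -> int:
        return len(self._bins)

    @property
    def n_singletons(self) -> int:
        return sum(1 for b in self._bins.values() if b.size == 1)

    @property
    def n_trees(self) -> int:
        return sum(b.size for b in self._bins.values())

    def __len__(self) -> int:
        return self.n_bins

    def __iter__(self):
        return iter(self.bins())


def bin_trees(forest: RawForest, index: TaxonIndex) -> BinTable:
    """Bin a forest by exact unrooted topology.

    All trees must share one taxon set (validate or prune first)."""
    taxon_sets = {e.tree.taxa() for e in forest}
    if len(taxon_sets) > 1:
        raise ValueError(
            "heterogeneous taxon sets in forest; validate or prune before binning"
        )
    table = BinTable(index)
    for e in forest:
        nf = normalize(e.tree, index)
        table.insert(nf, e.name, e.tree)
    return table


def average_tree(trees: list[PhyloTree], index: TaxonIndex) -> PhyloTree:
    """Representative tree for a set of topologically identical trees:
    the shared topology with each branch length the arithmetic mean of the
    members' corresponding lengths (missing lengths are excluded from the
    mean; all-missing stays missing).  Supports are averaged the same
    way."""
    if not trees:
        raise ValueError("empty bin: no trees to average")
    normalized = []
    keys = set()
    for t in trees:
        nf, nt = normalized_tree(t, index)
        normalized.append(nt.root)
        keys.add(nf.key)
    if len(keys) > 1:
        raise ValueError("trees do not share one topology; cannot average")

    def mean(values: list[float]) -> Optional[float]:
        present = [v for v in values if v is not None]
        return sum(present) / len(present) if present else None

    def merge(parallel: list[Node]) -> Node:
        first = parallel[0]
        out = Node(
            first.label,
            mean([nd.length for nd in parallel]),
            mean([nd.support for nd in parallel]),
        )
        for i in range(len(first.children)):
            out.add(merge([nd.children[i] for nd in parallel]))
        return out

    return PhyloTree(merge(normalized))
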