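"""Deterministic generators of synthetic gene-tree forests.

Emulates the structure of a genome-wide ortholog tree set over a shared
taxon panel: a dominant topology plus minority topologies, log-normal
branch-length noise, a controllable fraction of very short internal
branches (the noise that branch-length collapsing removes), bootstrap
annotations, and (for tolerant-mode tests) per-tree missing taxa.  Every
generator is a pure function of its seed, so fixtures are reproducible
byte-for-byte.

Topologies are produced by sequential random leaf attachment.  That is
not the uniform distribution over unrooted topologies; tests need
coverage and determinism, not a uniform prior.  ``enumerate_topologies``
provides exhaustive enumeration at small ``n`` — there are
(2n-5)!! unrooted binary topologies on n labeled leaves (15 at n=5,
105 at n=6) — for soundness/completeness checks.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterator, Optional

import numpy as np

from .newick_io import ForestEntry, RawForest, write_newick
from .tree_core import Node, PhyloTree, TaxonIndex, internal_nodes, reroot_at


def default_taxa(n_taxa: int) -> list[str]:
    return [f"t{i:02d}" for i in range(n_taxa)]


# ---------------------------------------------------------------------------
# random and exhaustive topology generation
# ---------------------------------------------------------------------------

def random_binary_tree(
    n_taxa: int,
    seed: int | np.random.Generator,
    taxa: Optional[list[str]] = None,
    length_mean: float = -3.0,
    length_sd: float = 1.0,
) -> PhyloTree:
    """Random unrooted binary topology by sequential random leaf
    attachment, with log-normal branch lengths.

    ``length_mean``/``length_sd`` are on the log scale; the defaults give
    lengths centered near 0.05 substitutions/site, the scale typical of
    single-gene trees from closely related bacterial strains.
    """
    if n_taxa < 3:
        raise ValueError("need at least 3 taxa for an unrooted topology")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if taxa is None:
        taxa = default_taxa(n_taxa)
    if len(taxa) != n_taxa:
        raise ValueError("taxa list length must equal n_taxa")

    def bl() -> float:
        return float(rng.lognormal(length_mean, length_sd))

    root = Node(children=[Node(label=taxa[0], length=bl()),
                          Node(label=taxa[1], length=bl()),
                          Node(label=taxa[2], length=bl())])
    tree = PhyloTree(root)
    for label in taxa[3:]:
        # every non-root node subtends one edge of the unrooted topology
        edges = [nd for nd in tree.iter_nodes() if nd is not root]
        target = edges[int(rng.integers(len(edges)))]
        parent = _parent_of(root, target)
        new_internal = Node(length=bl(), children=[target, Node(label=label, length=bl())])
        parent.children[parent.children.index(target)] = new_internal
    return tree


def _parent_of(root: Node, target: Node) -> Node:
    stack = [root]
    while stack:
        nd = stack.pop()
        for c in nd.children:
            if c is target:
                return nd
            stack.append(c)
    raise ValueError("target node not in tree")


def enumerate_topologies(taxa: list[str]) -> Iterator[PhyloTree]:
    """All distinct unrooted binary topologies on the given leaves,
    each produced exactly once (topology only, no branch lengths)."""
    if len(taxa) < 3:
        raise ValueError("need at least 3 taxa")

    def extend(tree: PhyloTree, remaining: list[str]) -> Iterator[PhyloTree]:
        if not remaining:
            yield tree
            return
        label, rest = remaining[0], remaining[1:]
        root = tree.root
        attach_points = [nd for nd in tree.iter_nodes() if nd is not root]
        for k in range(len(attach_points)):
            t2 = tree.copy()
            root2 = t2.root
            targets = [nd for nd in t2.iter_nodes() if nd is not root2]
            target = targets[k]
            parent = _parent_of(root2, target)
            parent.children[parent.children.index(target)] = Node(
                children=[target, Node(label=label)]
            )
            yield from extend(t2, rest)

    base = PhyloTree(Node(children=[Node(label=taxa[0]), Node(label=taxa[1]), Node(label=taxa[2])]))
    yield from extend(base, list(taxa[3:]))


# ---------------------------------------------------------------------------
# perturbations
# ---------------------------------------------------------------------------

def nni_perturb(
    tree: PhyloTree, moves: int, seed: int | np.random.Generator
) -> PhyloTree:
    """Apply ``moves`` random nearest-neighbor interchanges.

    Each NNI swaps a subtree across one internal edge, so the RF distance
    to the original is at most ``2 * moves`` (a move can also cancel a
    previous one).  The tree must have at least one internal edge.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = tree.copy()
    root = out.root
    for _ in range(moves):
        # internal edges = internal non-root nodes
        candidates = [
            nd for nd in out.iter_nodes() if not nd.is_leaf and nd is not root
        ]
        if not candidates:
            raise ValueError("no internal edge available for an NNI move")
        child = candidates[int(rng.integers(len(candidates)))]
        parent = _parent_of(root, child)
        siblings = [c for c in parent.children if c is not child]
        sib = siblings[int(rng.integers(len(siblings)))]
        grandchildren = child.children
        gc = grandchildren[int(rng.integers(len(grandchildren)))]
        # swap subtree gc (below the edge) with sibling sib (above it)
        parent.children[parent.children.index(sib)] = gc
        child.children[child.children.index(gc)] = sib
    return out


def shuffle_children(tree: PhyloTree, seed: int | np.random.Generator) -> PhyloTree:
    """Randomly permute every node's child order (topology-preserving)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = tree.copy()
    for nd in out.iter_nodes():
        if len(nd.children) > 1:
            order = rng.permutation(len(nd.children))
            nd.children = [nd.children[i] for i in order]
    return out


def random_rooting(tree: PhyloTree, seed: int | np.random.Generator) -> PhyloTree:
    """Re-root at a random internal node of the unrooted topology."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    internals = internal_nodes(tree)
    return reroot_at(tree, internals[int(rng.integers(len(internals)))])


# ---------------------------------------------------------------------------
# forest generation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ForestSpec:
    """Recipe for a synthetic forest with known ground truth.

    Defaults emulate a small ortholog panel: 10 taxa (the scale of a
    within-genus bacterial comparison), one dominant topology with two
    minority topologies, log-normal branch lengths centered near 0.05
    with occasional very short internal branches below ``short_branch_eps``,
    and integer bootstrap supports drawn uniformly from 60-100.
    """

    n_taxa: int = 10
    copies_per_topology: tuple[int, ...] = (5, 3, 2)
    length_mean: float = -3.0
    length_sd: float = 1.0
    short_branch_rate: float = 0.0
    short_branch_eps: float = 1e-3
    support_range: tuple[int, int] = (60, 100)
    with_support: bool = True
    missing_taxa_rate: float = 0.0
    min_pairwise_rf: int = 4
    seed: int = 0

    @property
    def n_topologies(self) -> int:
        return len(self.copies_per_topology)

    @property
    def n_trees(self) -> int:
        return sum(self.copies_per_topology)


def make_forest(spec: ForestSpec) -> tuple[RawForest, dict[str, int]]:
    """Generate a forest with planted bin structure.

    Returns the forest and a ground-truth map tree name -> planted
    topology id.  Base topologies are drawn until pairwise RF distances
    are all >= ``spec.min_pairwise_rf``; each copy then gets fresh branch
    lengths, a random rooting and shuffled child orders, so recovering
    the planted bins genuinely exercises normalization.

    When ``short_branch_rate`` is positive, a fixed subset of each base
    topology's internal edges is designated *short*: every copy draws
    those edge lengths below ``short_branch_eps``, and each copy may be
    NNI-flipped across a short edge.  This emulates estimation noise on
    poorly resolved branches — the copies are then near-duplicates whose
    bins a length collapse at a threshold above ``short_branch_eps``
    merges back into one bin per planted topology.
    """
    from .normalform import normalize
    from .rf import rf_pair

    rng = np.random.default_rng(spec.seed)
    taxa = default_taxa(spec.n_taxa)
    index = TaxonIndex(taxa)

    bases: list[PhyloTree] = []
    guard = 0
    while len(bases) < spec.n_topologies:
        cand = random_binary_tree(
            spec.n_taxa, rng, taxa, spec.length_mean, spec.length_sd
        )
        ok = all(
            rf_pair(cand, b, index) >= spec.min_pairwise_rf for b in bases
        )
        if ok:
            bases.append(cand)
        guard += 1
        if guard > 1000 * spec.n_topologies:
            raise RuntimeError(
                "could not plant topologies at the requested RF separation"
            )

    entries: list[ForestEntry] = []
    truth: dict[str, int] = {}
    tree_no = 0
    for topo_id, (base, copies) in enumerate(zip(bases, spec.copies_per_topology)):
        # short edges are a property of the planted topology, shared by
        # every copy (a poorly resolved branch is short in all estimates)
        short_paths = _pick_short_edges(base, rng, spec.short_branch_rate)
        for _ in range(copies):
            t = _redraw_lengths(base, rng, spec, short_paths)
            t = random_rooting(t, rng)
            t = shuffle_children(t, rng)
            if spec.missing_taxa_rate > 0:
                t = _drop_taxa(t, rng, spec.missing_taxa_rate)
            name = f"gene{tree_no:04d}"
            entries.append(ForestEntry(name=name, tree=t))
            truth[name] = topo_id
            tree_no += 1
    forest = RawForest(entries)
    # sanity: planted structure must be recoverable when copies are exact
    if spec.missing_taxa_rate == 0 and spec.short_branch_rate == 0:
        keys = {name: normalize(e.tree, index).key for name, e in zip(truth, entries)}
        assert len({keys[n] for n in keys}) == spec.n_topologies
    return forest, truth


def _node_at(root: Node, path: tuple[int, ...]) -> Node:
    nd = root
    for i in path:
        nd = nd.children[i]
    return nd


def _pick_short_edges(
    base: PhyloTree, rng: np.random.Generator, rate: float
) -> list[tuple[int, ...]]:
    """Child-index paths of the internal non-root edges designated short."""
    if rate <= 0:
        return []
    paths: list[tuple[int, ...]] = []

    def walk(nd: Node, path: tuple[int, ...]) -> None:
        for i, c in enumerate(nd.children):
            cpath = path + (i,)
            if not c.is_leaf:
                if rng.random() < rate:
                    paths.append(cpath)
                walk(c, cpath)

    walk(base.root, ())
    return paths


def _redraw_lengths(
    base: PhyloTree,
    rng: np.random.Generator,
    spec: ForestSpec,
    short_paths: list[tuple[int, ...]] = (),
) -> PhyloTree:
    t = base.copy()
    root = t.root
    for nd in t.iter_nodes():
        if nd is root:
            continue
        nd.length = float(rng.lognormal(spec.length_mean, spec.length_sd))
        if not nd.is_leaf and spec.with_support:
            lo, hi = spec.support_range
            nd.support = float(rng.integers(lo, hi + 1))
    # resolve the short-edge nodes before any modification: NNI flips
    # relocate subtrees, which would invalidate later paths
    short_nodes = [_node_at(root, path) for path in short_paths]
    for child in short_nodes:
        child.length = float(rng.uniform(0, spec.short_branch_eps))
    for child in short_nodes:
        if rng.random() < 0.5:
            # estimation noise: flip the copy across the short edge (NNI)
            parent = _parent_of(root, child)
            siblings = [c for c in parent.children if c is not child]
            sib = siblings[int(rng.integers(len(siblings)))]
            gc = child.children[int(rng.integers(len(child.children)))]
            parent.children[parent.children.index(sib)] = gc
            child.children[child.children.index(gc)] = sib
    return t


def _drop_taxa(
    tree: PhyloTree, rng: np.random.Generator, rate: float
) -> PhyloTree:
    from .preprocess import prune_taxa

    taxa = sorted(tree.taxa())
    keep = {t for t in taxa if rng.random() >= rate}
    if len(keep) < 3:
        keep = set(taxa[:3]) | keep
    return prune_taxa(tree, keep)


def write_fixture_forest(
    spec: ForestSpec, outdir: str
) -> tuple[RawForest, dict[str, int]]:
    """Write a generated forest to ``outdir`` as one ``.nwk`` file per
    tree plus a ``ground_truth.tsv`` (tree name, planted topology id)."""
    forest, truth = make_forest(spec)
    os.makedirs(outdir, exist_ok=True)
    for e in forest:
        with open(os.path.join(outdir, e.name + ".nwk"), "w") as fh:
            fh.write(write_newick(e.tree) + "\n")
    with open(os.path.join(outdir, "ground_truth.tsv"), "w") as fh:
        fh.write("tree\ttopology_id\n")
        for name, topo in truth.items():
            fh.write(f"{name}\t{topo}\n")
    return forest, truth
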