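"""Read/write Newick trees and forests, map gene labels to taxon names,
and validate forest consistency before analysis.

Parsing is delegated to dendropy (robust, position-reporting errors for
malformed input); the parsed tree is converted into the package's own
:class:`~treebin.tree_core.PhyloTree`.  Internal node labels that parse as
numbers are interpreted as support values (the convention of RAxML-style
bootstrap annotation); quoted labels and ``[]`` comments follow standard
Newick rules, and underscores are kept as literal underscores.
"""

from __future__ import annotations

import glob
import os
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import dendropy

from .tree_core import Node, PhyloTree, clamp_negative_lengths


class NewickParseError(ValueError):
    """Malformed Newick input; the message names the offending position."""


class ForestError(ValueError):
    """A forest-level consistency problem (duplicate names, empty forest...)."""


# ---------------------------------------------------------------------------
# single-tree parse / write
# ---------------------------------------------------------------------------

def parse_newick(text: str) -> PhyloTree:
    """Parse one Newick statement into a :class:`PhyloTree`.

    Absent branch lengths are recorded as missing (``None``), never 0.
    A numeric internal-node label is retained as that node's support
    value.  Malformed input (unbalanced parentheses, trailing garbage,
    duplicate leaf labels, empty input) raises :class:`NewickParseError`
    naming the position.
    """
    if not text.strip():
        raise NewickParseError("empty input: expected one Newick statement")
    _reject_trailing_content(text)
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy error classes vary; wrap uniformly
        raise NewickParseError(str(exc)) from None
    tree = PhyloTree(_from_dendropy(dtree.seed_node))
    try:
        tree.validate()
    except ValueError as exc:
        raise NewickParseError(str(exc)) from None
    clamp_negative_lengths(tree)
    return tree


def _reject_trailing_content(text: str) -> None:
    """Error (with position) on any non-whitespace after the terminating
    ';' — one statement means one statement.  Quoted labels and []
    comments may themselves contain ';'."""
    in_quote = False
    depth_comment = 0
    for pos, ch in enumerate(text):
        if in_quote:
            if ch == "'":
                in_quote = False
            continue
        if depth_comment:
            if ch == "]":
                depth_comment -= 1
            continue
        if ch == "'":
            in_quote = True
        elif ch == "[":
            depth_comment += 1
        elif ch == ";":
            rest = text[pos + 1:]
            if rest.strip():
                raise NewickParseError(
                    f"trailing content after ';' at position {pos + 1}: "
                    f"{rest.strip()[:40]!r}"
                )
            return


def _from_dendropy(dnode) -> Node:
    children = dnode.child_nodes()
    if not children:
        label = dnode.taxon.label if dnode.taxon is not None else dnode.label
        return Node(label=label, length=dnode.edge.length)
    support: Optional[float] = None
    label = dnode.label
    if label is not None:
        try:
            support = float(label)
        except ValueError:
            support = None
    nd = Node(length=dnode.edge.length, support=support)
    for c in children:
        nd.add(_from_dendropy(c))
    return nd


def _quote_label(label: str) -> str:
    safe = all(ch.isalnum() or ch in "_.-" for ch in label)
    if safe and label:
        return label
    return "'" + label.replace("'", "''") + "'"


def write_newick(
    tree: PhyloTree,
    include_lengths: bool = True,
    include_support: bool = True,
) -> str:
    """Serialize a tree to a Newick string, children in stored order.

    Round-trip property: ``parse_newick(write_newick(t))`` recovers the
    topology with equal lengths/support wherever present.
    """

    def emit(nd: Node, is_root: bool) -> str:
        if nd.is_leaf:
            s = _quote_label(nd.label)
        else:
            s = "(" + ",".join(emit(c, False) for c in nd.children) + ")"
            if include_support and nd.support is not None and not is_root:
                sup = nd.support
                s += repr(int(sup)) if float(sup).is_integer() else repr(sup)
        if include_lengths and nd.length is not None and not is_root:
            s += ":" + repr(nd.length)
        return s

    return emit(tree.root, True) + ";"


# ---------------------------------------------------------------------------
# forests
# ---------------------------------------------------------------------------

@dataclass
class ForestEntry:
    name: str
    tree: PhyloTree
    path: Optional[str] = None


@dataclass
class RawForest:
    """Ordered collection of named gene trees."""

    entries: list[ForestEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [e.name for e in self.entries]
        if len(set(names)) != len(names):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise ForestError(f"duplicate tree names in forest: {dup}")
        for e in self.entries:
            if e.tree.n_leaves < 2:
                raise ForestError(f"tree {e.name!r} has fewer than 2 leaves")

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def names(self) -> list[str]:
        return [e.name for e in self.entries]

    def trees(self) -> list[PhyloTree]:
        return [e.tree for e in self.entries]


def read_forest(paths: Sequence[str] | str) -> RawForest:
    """Read a forest from a directory, a glob pattern, or an explicit list
    of Newick files (one tree per file; tree name = basename sans
    extension).  Files that fail to parse raise; use
    :func:`read_forest_lenient` to collect errors instead."""
    forest, errors = read_forest_lenient(paths)
    if errors:
        name, msg = errors[0]
        raise NewickParseError(f"{name}: {msg}")
    return forest


def read_forest_lenient(
    paths: Sequence[str] | str,
) -> tuple[RawForest, list[tuple[str, str]]]:
    """Like :func:`read_forest`, but unparseable files are reported in a
    ``(path, message)`` list instead of aborting the run."""
    files = _expand_paths(paths)
    if not files:
        raise ForestError(f"no Newick files found under {paths!r}")
    entries: list[ForestEntry] = []
    errors: list[tuple[str, str]] = []
    for path in files:
        with open(path) as fh:
            text = fh.read()
        name = os.path.splitext(os.path.basename(path))[0]
        try:
            tree = parse_newick(text)
        except NewickParseError as exc:
            errors.append((path, str(exc)))
            continue
        entries.append(ForestEntry(name=name, tree=tree, path=path))
    return RawForest(entries), errors


_NEWICK_EXTS = (".nwk", ".newick", ".tre", ".tree", ".txt")


def _expand_paths(paths: Sequence[str] | str) -> list[str]:
    if isinstance(paths, str):
        paths = [paths]
    files: list[str] = []
    for p in paths:
        if os.path.isdir(p):
            for fn in sorted(os.listdir(p)):
                if fn.lower().endswith(_NEWICK_EXTS):
                    files.append(os.path.join(p, fn))
        elif any(ch in p for ch in "*?["):
            files.extend(sorted(glob.glob(p)))
        else:
            files.append(p)
    return files


# ---------------------------------------------------------------------------
# label rules
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LabelRule:
    """Gene-label -> taxon-name mapping rule.

    Modes: ``identity`` (labels used as-is); ``split`` (split the label on
    a delimiter, keep one field — e.g. ``wMel_WD0470`` with delimiter
    ``_``, field 0 gives ``wMel``); ``table`` (explicit mapping, matched
    exactly first, then by longest prefix)."""

    mode: str = "identity"
    delimiter: str = "_"
    fieldnum: int = 0
    table: Optional[dict[str, str]] = None

    @classmethod
    def identity(cls) -> "LabelRule":
        return cls(mode="identity")

    @classmethod
    def split(cls, delimiter: str, fieldnum: int = 0) -> "LabelRule":
        return cls(mode="split", delimiter=delimiter, fieldnum=fieldnum)

    @classmethod
    def from_table(cls, table: dict[str, str]) -> "LabelRule":
        return cls(mode="table", table=dict(table))

    @classmethod
    def from_table_file(cls, path: str) -> "LabelRule":
        """Two-column whitespace-separated file: gene-label-prefix, taxon."""
        table: dict[str, str] = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split()
                if len(parts) != 2:
                    raise ForestError(
                        f"{path}:{lineno}: expected two columns, got {len(parts)}"
                    )
                table[parts[0]] = parts[1]
        return cls.from_table(table)

    def apply(self, label: str) -> str:
        if self.mode == "identity":
            return label
        if self.mode == "split":
            parts = label.split(self.delimiter)
            if self.fieldnum >= len(parts):
                raise ForestError(
                    f"label {label!r}: no field {self.fieldnum} when split "
                    f"on {self.delimiter!r}"
                )
            return parts[self.fieldnum]
        if self.mode == "table":
            assert self.table is not None
            if label in self.table:
                return self.table[label]
            # longest-prefix match
            best = None
            for key in self.table:
                if label.startswith(key) and (best is None or len(key) > len(best)):
                    best = key
            if best is None:
                raise ForestError(f"label {label!r}: no mapping rule matches")
            return self.table[best]
        raise ValueError(f"unknown label-rule mode {self.mode!r}")


def relabel_forest(forest: RawForest, rule: LabelRule) -> RawForest:
    """Replace every leaf label by its taxon name under ``rule``.

    Errors name the tree and offending label; two leaves of one tree
    mapping to the same taxon is an error (the taxa of a gene tree must be
    distinct)."""
    if rule.mode == "identity":
        return forest
    entries = []
    for e in forest:
        tree = e.tree.copy()
        seen: dict[str, str] = {}
        for nd in tree.iter_nodes():
            if nd.is_leaf:
                try:
                    taxon = rule.apply(nd.label)
                except ForestError as exc:
                    raise ForestError(f"tree {e.name!r}: {exc}") from None
                if taxon in seen:
                    raise ForestError(
                        f"tree {e.name!r}: labels {seen[taxon]!r} and "
                        f"{nd.label!r} both map to taxon {taxon!r}"
                    )
                seen[taxon] = nd.label
                nd.label = taxon
        entries.append(ForestEntry(name=e.name, tree=tree, path=e.path))
    return RawForest(entries)


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

@dataclass
class RejectedTree:
    name: str
    reason: str
    missing: frozenset[str] = frozenset()
    extra: frozenset[str] = frozenset()


@dataclass
class ValidationReport:
    rejected: list[RejectedTree] = field(default_factory=list)
    majority_taxa: frozenset[str] = frozenset()
    taxa_union: frozenset[str] = frozenset()
    taxa_intersection: frozenset[str] = frozenset()

    def summary_lines(self) -> list[str]:
        lines = [
            f"taxa (majority set): {len(self.majority_taxa)}",
            f"taxa (union): {len(self.taxa_union)}",
            f"taxa (intersection): {len(self.taxa_intersection)}",
            f"rejected trees: {len(self.rejected)}",
        ]
        for r in self.rejected:
            lines.append(f"  {r.name}: {r.reason}")
        return lines


def validate_forest(
    forest: RawForest, tolerant: bool = False
) -> tuple[RawForest, ValidationReport]:
    """Split a forest into a clean part and a report of rejected trees.

    In the default (strict) mode, the clean forest contains exactly the
    trees whose taxon set equals the *majority* taxon set — the most
    frequent exact set, ties broken by the larger set; every other tree is
    rejected with its taxon-set difference spelled out.  In tolerant mode
    (unequal taxon sets are compared pairwise downstream) only per-tree
    well-formedness is checked and the union/intersection of taxon sets is
    recorded.
    """
    if len(forest) == 0:
        raise ForestError("empty forest: nothing to validate")
    taxon_sets = [e.tree.taxa() for e in forest]
    union = frozenset().union(*taxon_sets)
    inter = frozenset(taxon_sets[0]).intersection(*taxon_sets[1:])
    if tolerant:
        report = ValidationReport(
            rejected=[],
            majority_taxa=frozenset(),
            taxa_union=union,
            taxa_intersection=inter,
        )
        return forest, report

    counts: dict[frozenset[str], int] = {}
    for ts in taxon_sets:
        counts[ts] = counts.get(ts, 0) + 1
    majority = max(counts, key=lambda ts: (counts[ts], len(ts), sorted(ts)))
    clean_entries: list[ForestEntry] = []
    rejected: list[RejectedTree] = []
    for e, ts in zip(forest, taxon_sets):
        if ts == majority:
            clean_entries.append(e)
        else:
            missing = majority - ts
            extra = ts - majority
            bits = []
            if missing:
                bits.append(f"missing taxa {sorted(missing)}")
            if extra:
                bits.append(f"extra taxa {sorted(extra)}")
            rejected.append(
                RejectedTree(
                    name=e.name,
                    reason="; ".join(bits),
                    missing=frozenset(missing),
                    extra=frozenset(extra),
                )
            )
    report = ValidationReport(
        rejected=rejected,
        majority_taxa=majority,
        taxa_union=union,
        taxa_intersection=inter,
    )
    return RawForest(clean_entries), report
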