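"""Robinson–Foulds distances: a slow pairwise computation, the fast
all-pairs matrix via shared-bipartition hashing, and the tolerant-mode
pairwise matrix for trees with unequal taxon sets.

The distance between two trees on one taxon set is the size of the
symmetric difference of their nontrivial split sets, ``|S(a) Δ S(b)|``
(the full count; two binary trees on ``n`` taxa are at most ``2(n-3)``
apart).  Some tools report half this value; :func:`halved` converts a
matrix to that convention (odd counts, possible for multifurcating
trees, round half up).

The all-pairs matrix uses the two-phase shared-split strategy: every
tree's splits are first inserted into one global occurrence structure
keyed by the exact canonical bitset (so "hash" collisions are impossible
by construction), then shared-split counts ``s[i][j]`` are accumulated
from each split's occurrence list and
``d[i][j] = |S(i)| + |S(j)| - 2 s[i][j]``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .newick_io import RawForest
from .preprocess import IncomparableTreesError, restrict_to_common
from .tree_core import PhyloTree, TaxonIndex, bipartitions_of


@dataclass
class DistanceMatrix:
    """Symmetric integer RF-distance matrix with tree-name row labels.

    ``missing`` flags pairs that could not be compared (tolerant mode,
    fewer than 3 shared taxa); their ``data`` entries are 0 and must not
    be interpreted as distances.
    """

    labels: list[str]
    data: np.ndarray
    missing: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        n = len(self.labels)
        if self.data.shape != (n, n):
            raise ValueError("matrix shape does not match label count")
        if self.missing is None:
            self.missing = np.zeros((n, n), dtype=bool)

    @property
    def n(self) -> int:
        return len(self.labels)

    def has_missing(self) -> bool:
        return bool(self.missing.any())

    def __getitem__(self, pair: tuple[int, int]) -> int:
        return int(self.data[pair])

    def fill_missing(self, value: int) -> "DistanceMatrix":
        """A copy with missing entries replaced by ``value`` (a fill
        policy for clustering forests with incomparable pairs)."""
        data = self.data.copy()
        data[self.missing] = value
        return DistanceMatrix(
            labels=list(self.labels),
            data=data,
            missing=np.zeros_like(self.missing),
        )

    def to_text(self) -> str:
        """Tab-separated lower-triangular serialization: a header line of
        tree names, then one row per tree (name + distances to all
        previous trees).  Missing entries print as ``NA``."""
        lines = ["\t".join(self.labels)]
        for i, name in enumerate(self.labels):
            cells = [name]
            for j in range(i):
                cells.append("NA" if self.missing[i, j] else str(int(self.data[i, j])))
            lines.append("\t".join(cells))
        return "\n".join(lines) + "\n"


def rf_pair(a: PhyloTree, b: PhyloTree, index: TaxonIndex) -> int:
    """Robinson–Foulds distance between two trees on one taxon set.

    Pairs on fewer than 3 taxa have no nontrivial split and are at
    distance 0 by definition."""
    ta, tb = a.taxa(), b.taxa()
    if ta != tb:
        raise ValueError(
            "taxon sets differ; use the tolerant path (rf_matrix_tolerant) "
            "or restrict_to_common first"
        )
    if len(ta) < 3:
        return 0
    sa = bipartitions_of(a, index)
    sb = bipartitions_of(b, index)
    return len(sa.symmetric_difference(sb))


def rf_matrix(forest: RawForest, index: TaxonIndex) -> DistanceMatrix:
    """All-pairs RF matrix via the two-phase shared-bipartition method.

    Identical to entrywise :func:`rf_pair`, but each tree's splits are
    enumerated once and shared counts come from a single global
    occurrence structure."""
    taxon_sets = {e.tree.taxa() for e in forest}
    if len(taxon_sets) > 1:
        raise ValueError(
            "heterogeneous taxon sets; use rf_matrix_tolerant for unequal taxa"
        )
    labels = forest.names()
    n_trees = len(labels)
    # phase 1: global split-occurrence structure
    occurrence: dict[int, list[int]] = {}
    split_counts = np.zeros(n_trees, dtype=np.int64)
    for i, e in enumerate(forest):
        splits = bipartitions_of(e.tree, index)
        split_counts[i] = len(splits)
        for s in splits:
            occurrence.setdefault(s, []).append(i)
    # phase 2: shared-split accumulation via the occurrence incidence matrix
    shared = np.zeros((n_trees, n_trees), dtype=np.int64)
    if occurrence:
        incidence = np.zeros((n_trees, len(occurrence)), dtype=np.int64)
        for col, members in enumerate(occurrence.values()):
            incidence[members, col] = 1
        shared = incidence @ incidence.T
    d = split_counts[:, None] + split_counts[None, :] - 2 * shared
    np.fill_diagonal(d, 0)
    return DistanceMatrix(labels=labels, data=d)


def rf_matrix_tolerant(
    forest: RawForest,
) -> tuple[DistanceMatrix, list[tuple[str, str, str]]]:
    """Pairwise RF matrix for trees with unequal taxon sets.

    Each pair is pruned to its common taxa (see
    :func:`~treebin.preprocess.restrict_to_common`) and compared with
    :func:`rf_pair` over a pair-local taxon index — an O(T^2) pairwise
    computation, unlike the shared-split fast path.  Pairs sharing fewer
    than 3 taxa get a missing entry; the second return value reports them
    as ``(name_i, name_j, reason)``.
    """
    labels = forest.names()
    n_trees = len(labels)
    data = np.zeros((n_trees, n_trees), dtype=np.int64)
    missing = np.zeros((n_trees, n_trees), dtype=bool)
    problems: list[tuple[str, str, str]] = []
    entries = list(forest)
    for i in range(n_trees):
        for j in range(i + 1, n_trees):
            a, b = entries[i].tree, entries[j].tree
            try:
                pa, pb = restrict_to_common(a, b)
            except IncomparableTreesError as exc:
                missing[i, j] = missing[j, i] = True
                problems.append((labels[i], labels[j], str(exc)))
                continue
            pair_index = TaxonIndex(pa.taxa())
            d = rf_pair(pa, pb, pair_index)
            data[i, j] = data[j, i] = d
    return DistanceMatrix(labels=labels, data=data, missing=missing), problems


def halved(matrix: DistanceMatrix) -> DistanceMatrix:
    """Convert a full-count matrix to the one-sided convention: each
    entry becomes ``ceil(d / 2)`` (for binary same-taxa trees the two
    one-sided counts are equal and this is exact division)."""
    return DistanceMatrix(
        labels=list(matrix.labels),
        data=(matrix.data + 1) // 2,
        missing=matrix.missing.copy(),
    )
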