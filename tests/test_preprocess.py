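"""Branch collapsing and taxon pruning semantics."""

import numpy as np
import pytest

from treebin.fixtures import random_binary_tree
from treebin.newick_io import parse_newick, write_newick
from treebin.preprocess import (
    CollapseSpec,
    IncomparableTreesError,
    collapse_low_support,
    collapse_short_branches,
    prune_taxa,
    restrict_to_common,
)
from treebin.rf import rf_pair
from treebin.tree_core import TaxonIndex, bipartitions_of, suppress_unary


def _leaf_depths(tree):
    out = {}

    def walk(nd, acc):
        acc = acc + (nd.length or 0.0)
        if nd.is_leaf:
            out[nd.label] = acc
        for c in nd.children:
            walk(c, acc)

    walk(tree.root, 0.0)
    return out


class TestCollapseShortBranches:
    def test_short_internal_edge_contracted_to_polytomy(self):
        t = parse_newick("(A:1,B:1,(C:1,D:1):0.005,E:1);")
        out = collapse_short_branches(t, 0.01)
        assert len(out.root.children) == 5  # star: C and D re-attached
        idx = TaxonIndex(t.taxa())
        assert bipartitions_of(out, idx) == frozenset()

    def test_strict_inequality_at_threshold(self):
        t = parse_newick("(A:1,B:1,(C:1,D:1):0.01);")
        out = collapse_short_branches(t, 0.01)
        idx = TaxonIndex(t.taxa())
        assert len(bipartitions_of(out, idx)) == 1  # edge == threshold survives

    def test_threshold_zero_is_identity(self, rng):
        t = random_binary_tree(8, rng)
        idx = TaxonIndex(t.taxa())
        out = collapse_short_branches(t, 0.0)
        assert bipartitions_of(out, idx) == bipartitions_of(t, idx)

    def test_leaf_edges_never_contracted(self):
        t = parse_newick("(A:1e-9,B:1,(C:1,D:1):5);")
        out = collapse_short_branches(t, 1.0)
        assert sorted(out.leaf_labels()) == ["A", "B", "C", "D"]

    def test_missing_length_never_contracted(self):
        t = parse_newick("(A:1,B:1,(C:1,D:1));")
        out = collapse_short_branches(t, 100.0)
        idx = TaxonIndex(t.taxa())
        assert len(bipartitions_of(out, idx)) == 1

    def test_full_collapse_yields_star(self, rng):
        t = random_binary_tree(9, rng)
        idx = TaxonIndex(t.taxa())
        internal_max = max(
            nd.length
            for nd in t.iter_nodes()
            if not nd.is_leaf and nd is not t.root and nd.length is not None
        )
        out = collapse_short_branches(t, internal_max * 1.01)
        assert bipartitions_of(out, idx) == frozenset()

    def test_idempotent_and_composes_as_max(self, rng):
        for _ in range(10):
            t = random_binary_tree(10, rng)
            a, b = sorted(rng.uniform(0.001, 0.3, size=2))
            idx = TaxonIndex(t.taxa())
            once = collapse_short_branches(t, b)
            twice = collapse_short_branches(once, b)
            assert bipartitions_of(once, idx) == bipartitions_of(twice, idx)
            chained = collapse_short_branches(collapse_short_branches(t, a), b)
            direct = collapse_short_branches(t, max(a, b))
            assert bipartitions_of(chained, idx) == bipartitions_of(direct, idx)

    def test_rf_to_original_counts_removed_splits(self, rng):
        for _ in range(10):
            t = random_binary_tree(10, rng)
            idx = TaxonIndex(t.taxa())
            theta = float(rng.uniform(0.01, 0.2))
            out = collapse_short_branches(t, theta)
            removed = bipartitions_of(t, idx) - bipartitions_of(out, idx)
            assert bipartitions_of(out, idx) <= bipartitions_of(t, idx)
            assert rf_pair(t, out, idx) == len(removed)


class TestCollapseLowSupport:
    def test_lengths_added_through_dissolved_node(self):
        t = parse_newick("(A:2,B:2,(C:1.0,D:1.0)80:0.5);")
        out = collapse_low_support(t, 90)
        assert len(out.root.children) == 4
        depths = _leaf_depths(out)
        assert depths["C"] == pytest.approx(1.5)
        assert depths["D"] == pytest.approx(1.5)

    def test_high_support_kept(self):
        t = parse_newick("(A:2,B:2,(C:1,D:1)95:0.5);")
        out = collapse_low_support(t, 90)
        idx = TaxonIndex(t.taxa())
        assert len(bipartitions_of(out, idx)) == 1

    def test_threshold_equal_support_survives(self):
        t = parse_newick("(A:2,B:2,(C:1,D:1)90:0.5);")
        out = collapse_low_support(t, 90)
        assert len(bipartitions_of(out, TaxonIndex(t.taxa()))) == 1

    def test_unsupported_nodes_kept(self):
        t = parse_newick("(A:2,B:2,(C:1,D:1):0.5);")
        out = collapse_low_support(t, 101)
        assert len(bipartitions_of(out, TaxonIndex(t.taxa()))) == 1

    def test_full_collapse_preserves_leaf_path_lengths(self, rng):
        t = random_binary_tree(8, rng)
        for nd in t.iter_nodes():
            if not nd.is_leaf and nd is not t.root:
                nd.support = float(rng.integers(50, 100))
        before = _leaf_depths(suppress_unary(t))
        out = collapse_low_support(t, 101)
        assert bipartitions_of(out, TaxonIndex(t.taxa())) == frozenset()
        after = _leaf_depths(out)
        for taxon in before:
            assert after[taxon] == pytest.approx(before[taxon])

    def test_support_collapse_runs_before_length_collapse(self):
        # the dissolved node's length is added to its children, pushing the
        # child edge past the length threshold: it must survive
        t = parse_newick("((A:1,B:1)99:0.008,C:1,(D:1,(E:1,F:1)99:0.008)50:0.005);")
        out = CollapseSpec(min_branch_len=0.01, min_support=60).apply(t)
        idx = TaxonIndex(t.taxa())
        splits = bipartitions_of(out, idx)
        ef = (1 << idx.position("E")) | (1 << idx.position("F"))
        assert ef in splits  # 0.008 + 0.005 = 0.013 >= 0.01 after dissolution
        assert len(splits) == 1  # AB edge at 0.008 < 0.01 collapsed


class TestPrune:
    def test_binary_parent_suppressed_lengths_summed(self):
        t = parse_newick("((A:1,C:1):2,B:3,D:3);")
        out = prune_taxa(t, {"A", "B", "D"})
        depths = _leaf_depths(out)
        assert depths["A"] == pytest.approx(3.0)  # 1 + 2
        assert depths["B"] == pytest.approx(3.0)
        assert len(out.root.children) == 3

    def test_polytomy_parent_unchanged(self):
        t = parse_newick("(A:1,B:1,C:1,D:1);")
        out = prune_taxa(t, {"A", "B", "D"})
        assert write_newick(out) == "(A:1.0,B:1.0,D:1.0);"

    def test_keep_all_is_identity(self):
        t = parse_newick("(A:1,B:1,(C:1,D:1):2);")
        out = prune_taxa(t, set("ABCD"))
        assert write_newick(out) == write_newick(t)

    def test_too_few_survivors_is_error(self):
        t = parse_newick("(A,B,(C,D));")
        with pytest.raises(IncomparableTreesError):
            prune_taxa(t, {"A"})

    def test_prune_composes_as_intersection(self, rng):
        t = random_binary_tree(10, rng)
        taxa = sorted(t.taxa())
        keep1, keep2 = set(taxa[:7]), set(taxa[3:])
        both = prune_taxa(prune_taxa(t, keep1), keep2)
        direct = prune_taxa(t, keep1 & keep2)
        idx = TaxonIndex(keep1 & keep2)
        assert bipartitions_of(both, idx) == bipartitions_of(direct, idx)

    def test_prune_idempotent(self, rng):
        t = random_binary_tree(9, rng)
        keep = set(sorted(t.taxa())[:6])
        once = prune_taxa(t, keep)
        twice = prune_taxa(once, keep)
        idx = TaxonIndex(keep)
        assert bipartitions_of(once, idx) == bipartitions_of(twice, idx)


class TestRestrictToCommon:
    def test_prunes_to_intersection(self):
        a = parse_newick("(A,B,(C,(D,E)));")
        b = parse_newick("((A,B),C,D);")
        pa, pb = restrict_to_common(a, b)
        assert pa.taxa() == pb.taxa() == {"A", "B", "C", "D"}

    def test_identical_sets_identity(self):
        a = parse_newick("(A,B,(C,D));")
        b = parse_newick("(D,C,(B,A));")
        pa, pb = restrict_to_common(a, b)
        idx = TaxonIndex(a.taxa())
        assert bipartitions_of(pa, idx) == bipartitions_of(a, idx)

    def test_disjoint_sets_incomparable(self):
        a = parse_newick("(A,B,C);")
        b = parse_newick("(X,Y,Z);")
        with pytest.raises(IncomparableTreesError):
            restrict_to_common(a, b)
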