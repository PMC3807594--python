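"""Hierarchical clustering, flat cuts, consensus and dendrogram export."""

import numpy as np
import pytest

from treebin.cluster import (
    Clustering,
    dendrogram_to_dot,
    dendrogram_to_newick,
    flat_clusters,
    linkage,
    strict_consensus,
    summarize_clusters,
)
from treebin.fixtures import ForestSpec, enumerate_topologies, make_forest
from treebin.newick_io import ForestEntry, RawForest, parse_newick
from treebin.normalform import bin_trees, normalize
from treebin.rf import DistanceMatrix, rf_matrix
from treebin.tree_core import TaxonIndex, bipartitions_of

from conftest import make_random_forest


def dm(labels, entries):
    n = len(labels)
    data = np.zeros((n, n), dtype=np.int64)
    for (i, j), v in entries.items():
        data[i, j] = data[j, i] = v
    return DistanceMatrix(labels=labels, data=data)


def merge_heights(dend):
    return sorted(nd.height for nd in dend.iter_nodes() if not nd.is_leaf)


class TestLinkage:
    def test_single_chains_through_minimum(self):
        d = dm(["t1", "t2", "t3"], {(0, 1): 2, (1, 2): 2, (0, 2): 4})
        dend = linkage(d, "single")
        assert merge_heights(dend) == [2, 2]

    def test_complete_uses_maximum(self):
        d = dm(["t1", "t2", "t3"], {(0, 1): 2, (1, 2): 2, (0, 2): 4})
        dend = linkage(d, "complete")
        assert merge_heights(dend) == [2, 4]

    def test_upgma_weighted_mean(self):
        d = dm(["t1", "t2", "t3"], {(0, 1): 2, (0, 2): 4, (1, 2): 4})
        dend = linkage(d, "upgma")
        assert merge_heights(dend) == [2, 4]

    def test_upgma_size_weighting(self):
        # {a,b} and {c,d} merge at 2; the final height is the unweighted
        # mean over all four cross pairs, (4+6+8+8)/4 = 6.5, which the
        # size-weighted Lance-Williams update reproduces exactly
        d = dm(
            ["a", "b", "c", "d"],
            {(0, 1): 2, (0, 2): 4, (1, 2): 6, (0, 3): 8, (1, 3): 8, (2, 3): 2},
        )
        dend = linkage(d, "upgma")
        assert merge_heights(dend) == [2, 2, 6.5]

    def test_all_zero_matrix_merges_at_zero(self):
        d = dm(["a", "b", "c", "d"], {})
        dend = linkage(d, "upgma")
        assert merge_heights(dend) == [0, 0, 0]

    def test_matches_scipy_on_tie_free_matrix(self, rng):
        from scipy.cluster.hierarchy import linkage as scipy_linkage

        n = 12
        pts = rng.uniform(0, 100, size=(n, 3))
        data = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        d = DistanceMatrix(labels=[f"t{i:02d}" for i in range(n)], data=data)
        condensed = data[np.triu_indices(n, 1)]
        for mine, theirs in [("single", "single"), ("complete", "complete"),
                             ("upgma", "average")]:
            ours = merge_heights(linkage(d, mine))
            ref = sorted(scipy_linkage(condensed, method=theirs)[:, 2].tolist())
            assert ours == pytest.approx(ref)

    def test_deterministic_under_ties(self):
        d = dm(["a", "b", "c", "d"],
               {(0, 1): 2, (2, 3): 2, (0, 2): 6, (0, 3): 6, (1, 2): 6, (1, 3): 6})
        newicks = {dendrogram_to_newick(linkage(d, "upgma")) for _ in range(5)}
        assert len(newicks) == 1

    def test_missing_entries_rejected(self):
        d = dm(["a", "b", "c"], {(0, 1): 2})
        d.missing[0, 2] = d.missing[2, 0] = True
        with pytest.raises(ValueError, match="tolerant-fill"):
            linkage(d, "upgma")

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError):
            linkage(dm(["a", "b"], {(0, 1): 1}), "ward")


class TestFlatClusters:
    def test_threshold_zero_equals_bins(self):
        forest, _ = make_forest(ForestSpec(seed=5))
        idx = TaxonIndex.from_trees(forest.trees())
        table = bin_trees(forest, idx)
        dend = linkage(rf_matrix(forest, idx), "upgma")
        clusters = flat_clusters(dend, 0)
        bins_as_sets = {frozenset(b.member_names()) for b in table.bins()}
        assert clusters.as_sets() == bins_as_sets

    def test_threshold_at_root_height_single_cluster(self, rng):
        forest, idx = make_random_forest(rng, 8, 10)
        dend = linkage(rf_matrix(forest, idx), "complete")
        root_h = max(nd.height for nd in dend.iter_nodes())
        clusters = flat_clusters(dend, root_h)
        assert clusters.n_clusters == 1

    def test_planted_clusters_at_threshold_two(self):
        forest, truth = make_forest(ForestSpec(seed=5, min_pairwise_rf=4))
        idx = TaxonIndex.from_trees(forest.trees())
        dend = linkage(rf_matrix(forest, idx), "upgma")
        clusters = flat_clusters(dend, 2)
        assert clusters.sizes() == [5, 3, 2]
        by_truth = {}
        for name, topo in truth.items():
            by_truth.setdefault(topo, set()).add(name)
        assert clusters.as_sets() == {frozenset(v) for v in by_truth.values()}

    def test_single_linkage_equals_connected_components(self, rng):
        # independent graph oracle: clusters at theta = components of the
        # graph with an edge wherever d <= theta
        import networkx as nx

        for _ in range(5):
            forest, idx = make_random_forest(rng, 7, 12)
            m = rf_matrix(forest, idx)
            dend = linkage(m, "single")
            for theta in (0, 2, 4, 6):
                ours = flat_clusters(dend, theta).as_sets()
                g = nx.Graph()
                g.add_nodes_from(m.labels)
                for i in range(m.n):
                    for j in range(i):
                        if m[i, j] <= theta:
                            g.add_edge(m.labels[i], m.labels[j])
                components = {frozenset(c) for c in nx.connected_components(g)}
                assert ours == components

    def test_cluster_count_monotone_in_threshold(self, rng):
        forest, idx = make_random_forest(rng, 8, 15)
        dend = linkage(rf_matrix(forest, idx), "upgma")
        counts = [flat_clusters(dend, th).n_clusters for th in np.linspace(0, 12, 13)]
        assert counts == sorted(counts, reverse=True)

    def test_refinement_nesting(self, rng):
        # raising the threshold never splits an existing cluster
        forest, idx = make_random_forest(rng, 8, 15)
        dend = linkage(rf_matrix(forest, idx), "upgma")
        fine = flat_clusters(dend, 2).as_sets()
        coarse = flat_clusters(dend, 6).as_sets()
        for c in fine:
            assert any(c <= big for big in coarse)


class TestConsensus:
    def test_identical_trees_consensus_is_topology(self, rng):
        forest, idx = make_random_forest(rng, 7, 1)
        t = forest.entries[0].tree
        cons = strict_consensus([t, t.copy()], idx)
        assert normalize(cons, idx) == normalize(t, idx)

    def test_all_topologies_consensus_is_star(self):
        taxa = [f"t{i}" for i in range(5)]
        idx = TaxonIndex(taxa)
        cons = strict_consensus(list(enumerate_topologies(taxa)), idx)
        assert bipartitions_of(cons, idx) == frozenset()

    def test_single_shared_split_retained(self):
        a = parse_newick("((A,B),C,(D,E));")
        b = parse_newick("((A,C),B,(D,E));")
        idx = TaxonIndex(a.taxa())
        cons = strict_consensus([a, b], idx)
        splits = bipartitions_of(cons, idx)
        de = (1 << idx.position("D")) | (1 << idx.position("E"))
        assert splits == {de}

    def test_consensus_splits_subset_of_every_member(self, rng):
        forest, idx = make_random_forest(rng, 8, 6)
        cons = strict_consensus(forest.trees(), idx)
        cs = bipartitions_of(cons, idx)
        for t in forest.trees():
            assert cs <= bipartitions_of(t, idx)

    def test_heterogeneous_taxa_rejected(self):
        a = parse_newick("(A,B,(C,D));")
        b = parse_newick("(A,B,C);")
        with pytest.raises(ValueError):
            strict_consensus([a, b], TaxonIndex(["A", "B", "C", "D"]))


class TestDendrogramExport:
    def test_two_trees_merge_height_as_branch_lengths(self):
        d = dm(["t1", "t2"], {(0, 1): 2})
        dend = linkage(d, "upgma")
        assert dendrogram_to_newick(dend) == "(t1:2.0,t2:2.0);"

    def test_zero_matrix_zero_lengths(self):
        d = dm(["a", "b", "c"], {})
        nwk = dendrogram_to_newick(linkage(d, "upgma"))
        t = parse_newick(nwk)
        assert all(nd.length == 0 for nd in t.iter_nodes() if nd is not t.root)

    def test_round_trips_with_one_leaf_per_tree(self, rng):
        forest, idx = make_random_forest(rng, 7, 9)
        dend = linkage(rf_matrix(forest, idx), "upgma")
        t = parse_newick(dendrogram_to_newick(dend))
        assert sorted(t.leaf_labels()) == sorted(forest.names())

    def test_dot_output_names_all_trees(self, rng):
        forest, idx = make_random_forest(rng, 6, 5)
        dend = linkage(rf_matrix(forest, idx), "single")
        dot = dendrogram_to_dot(dend)
        assert dot.startswith("graph")
        for name in forest.names():
            assert name in dot


class TestSummaries:
    def test_uniform_cluster_representative_averages_lengths(self):
        forest, _ = make_forest(ForestSpec(seed=5))
        idx = TaxonIndex.from_trees(forest.trees())
        dend = linkage(rf_matrix(forest, idx), "upgma")
        clustering = flat_clusters(dend, 2)
        trees = {e.name: e.tree for e in forest}
        summaries = summarize_clusters(clustering, trees, idx)
        assert [s.size for s in summaries] == [5, 3, 2]
        for s in summaries:
            # zero-diameter clusters: consensus topology == member topology
            member_nf = normalize(trees[s.members[0]], idx)
            assert normalize(s.consensus, idx) == member_nf
            assert normalize(s.representative, idx) == member_nf
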