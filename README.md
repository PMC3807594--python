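# treebin

Batch binning and clustering of gene-tree topologies from Newick forests.

## The problem

Genome-scale phylogenetics produces one tree per orthologous gene — often
hundreds of trees over the same taxon panel. Individual genes can support
different evolutionary histories (incomplete lineage sorting, long-branch
artifacts, horizontal gene transfer), so a central question is: *how many
distinct topologies does an ortholog set actually contain, and which genes
support which history?* `treebin` answers this for precomputed forests of
non-reticulated Newick trees, as produced by RAxML, FastTree, IQ-TREE and
similar tools. It is a utility, not a pipeline: feed it whatever trees your
ortholog-detection and tree-building steps produced.

Two modes:

* **Binning** groups *exactly identical* unrooted topologies. Every input
  tree (a labeled, unrooted, unordered topology) is converted to a canonical
  **normal form**: the root is placed at the node that minimizes the maximum
  *weight* (node count) of any child subtree, children are ordered by
  descending weight with leaf-set bitsets breaking ties, and residual root
  ties are resolved by smallest serialization. Equal topology then means
  equal normal form, so bins fall out of ordered-map insertion.
* **Clustering** groups *similar* topologies. The Robinson–Foulds (RF)
  distance between trees `a`, `b` is `|S(a) Δ S(b)|`, the symmetric
  difference of their nontrivial bipartition (split) sets. The all-pairs
  matrix is computed in two phases — all splits into one global occurrence
  map keyed by exact bitset, then shared counts
  `d(i,j) = |S(i)| + |S(j)| − 2·s(i,j)` — followed by agglomerative
  hierarchical clustering (single, complete or UPGMA linkage) and a flat cut
  at a user-chosen edit-distance threshold. The dendrogram itself (a
  *tree of trees*) is written as Newick and DOT.

Preprocessing handles the noise real forests carry: collapse internal
branches shorter than a length threshold (inserting a polytomy), collapse
nodes under a bootstrap-support threshold (summing branch lengths through
the dissolved node), prune to a taxon subset, map gene labels like
`wMel_WD0470` to taxon names, and detect trees with mismatching taxon sets.
A `--tolerant` mode compares trees with unequal taxon sets by pruning each
pair to its common taxa.

## Worked example

Generate a small synthetic forest with three planted topologies
(5 + 3 + 2 = 10 trees over 10 taxa), then bin and cluster it:

```
$ treebin fixture --out demo_forest --copies 5,3,2 --seed 7
wrote 10 trees to demo_forest

$ treebin bin demo_forest --out demo_bins
10 trees -> 3 bins (0 singletons)

$ cat demo_bins/bins_summary.tsv
rank    size    members_file
1       5       bin001_5.members.txt
2       3       bin002_3.members.txt
3       2       bin003_2.members.txt

$ treebin cluster demo_forest --out demo_clusters --editdist 2 --UPGMA
10 trees -> 3 clusters at edit distance 2 (0 singletons)
```

The three bins recover the planted multiplicities exactly even though every
copy was given fresh branch lengths, a random rooting and shuffled child
orders — binning keys on topology alone. Clustering at edit distance 2
returns the same three groups because the planted topologies are at
pairwise RF ≥ 4: no two of them can fall in one cluster at threshold 2.
The cluster run additionally writes `distance_matrix.txt` (lower-triangular
RF distances), `dendrogram.nwk` / `dendrogram.dot` (the tree of trees) and
one strict-consensus Newick per cluster.

On noisy data, collapse weak branches first:

```
$ treebin bin my_trees/ --out out --minbranchlen 0.01 --minbootstrap 70
```

Every flag is also available from Python (`treebin.bin_trees`,
`treebin.rf_matrix`, `treebin.linkage`, `treebin.flat_clusters`, ...); the
CLI is a thin wrapper over the library.

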