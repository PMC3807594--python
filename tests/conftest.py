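import numpy as np
import pytest

from treebin.fixtures import random_binary_tree
from treebin.newick_io import ForestEntry, RawForest
from treebin.tree_core import TaxonIndex


def make_random_forest(rng, n_taxa, n_trees, prefix="t"):
    trees = [random_binary_tree(n_taxa, rng) for _ in range(n_trees)]
    forest = RawForest(
        [ForestEntry(name=f"{prefix}{i:03d}", tree=t) for i, t in enumerate(trees)]
    )
    return forest, TaxonIndex.from_trees(trees)


@pytest.fixture
def rng():
    return np.random.default_rng(20130187)


@pytest.fixture
def small_forest(rng):
    """12 random 8-taxon binary trees on one taxon set."""
    return make_random_forest(rng, 8, 12)
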