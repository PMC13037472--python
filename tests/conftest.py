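import io

import numpy as np
import pytest
from skbio import TreeNode

from phyloneutral.io_core import FeatureTable, Phylogeny, SampleMetadata


def make_phylogeny(newick: str, focal=()) -> Phylogeny:
    tree = TreeNode.read(io.StringIO(newick), format="newick")
    for node in tree.traverse(include_self=False):
        if node.length is None:
            node.length = 0.0
    return Phylogeny(tree=tree, focal=frozenset(focal))


@pytest.fixture
def tiny_table():
    return FeatureTable(["t1", "t2"], ["s1", "s2"], np.array([[1, 2], [3, 4]]))


@pytest.fixture
def toy_table():
    rng = np.random.default_rng(7)
    counts = rng.integers(0, 50, size=(6, 4))
    counts[0, :] = 0  # one all-zero taxon
    counts[:, 0] += 1  # no all-zero sample
    return FeatureTable(
        [f"t{i}" for i in range(6)], [f"s{j}" for j in range(4)], counts
    )


@pytest.fixture
def toy_metadata(toy_table):
    groups = {s: ("g1" if i < 2 else "g2") for i, s in enumerate(toy_table.sample_ids)}
    return SampleMetadata(groups=groups)


@pytest.fixture
def two_tip_phylogeny():
    return make_phylogeny("(A:1,B:1);", focal={"A"})
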