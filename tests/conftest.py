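import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from grainscape import OtuTable, TaxonomyMap, tree_from_string
from grainscape.synthetic import random_tree_newick


@pytest.fixture
def small_table():
    """3 samples x 4 OTUs with easily hand-checked totals."""
    data = pd.DataFrame(
        [[5, 1, 0, 4], [3, 0, 1, 6], [2, 1, 2, 5]],
        index=["s1", "s2", "s3"],
        columns=["otu_a", "otu_b", "otu_c", "otu_d"],
    )
    return OtuTable(data)


@pytest.fixture
def small_tree():
    return tree_from_string("((A:1,B:2):0.5,C:3);")


@pytest.fixture
def taxonomy():
    return TaxonomyMap({
        "otu_a": ("Bacteria", "P1", "C1", "O1", "FamX"),
        "otu_b": ("Bacteria", "P1", "C1", "O1", "FamX"),
        "otu_c": ("Bacteria", "P2", "C2", "O2", "FamY"),
        "otu_d": ("Bacteria", "P2", "C2", "O2", "FamY"),
    })


def random_fixture(rng: np.random.Generator, n_leaves: int = 12, n_samples: int = 2):
    """Random (newick, count DataFrame) pair for metric cross-checks."""
    labels = [f"L{i}" for i in range(n_leaves)]
    newick = random_tree_newick(labels, rng, branch_scale=0.5)
    counts = rng.integers(0, 20, size=(n_samples, n_leaves))
    for i in range(n_samples):  # every sample must observe something
        if counts[i].sum() == 0:
            counts[i, rng.integers(n_leaves)] = 1
    frame = pd.DataFrame(counts, index=[f"s{i}" for i in range(n_samples)], columns=labels)
    return newick, frame
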