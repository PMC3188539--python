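"""Shared fixtures: tiny hand-checkable inputs and one standard synthetic run."""

import numpy as np
import pytest

from lsckit import (
    MultipleAlignment,
    SimulationSpec,
    simulate_alignment,
    tree_from_newick,
)
from lsckit.counts import clade_site_counts


@pytest.fixture
def quartet_tree():
    return tree_from_newick("((a:1,b:1):1,(c:1,d:1):1);")


@pytest.fixture
def tiny_alignment():
    return MultipleAlignment(["a", "b", "c", "d"], ["KKAC", "KKAC", "DDAC", "DDA-"])


@pytest.fixture(scope="session")
def standard_dataset():
    """The standard synthetic fixture: two 16-leaf clades, 500 columns."""
    return simulate_alignment(SimulationSpec(seed=101))


@pytest.fixture(scope="session")
def standard_counts(standard_dataset):
    ds = standard_dataset
    return clade_site_counts(ds.aln, ds.trees, ds.partition, min_leaves=2)


def random_phylogeny(rng: np.random.Generator, n_leaves: int):
    """Random binary topology with exponential branch lengths (for oracles)."""
    labels = [f"t{i}" for i in range(n_leaves)]
    nodes = [f"{lab}:{rng.exponential(0.5) + 0.05:.4f}" for lab in labels]
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        nodes.append(f"({a},{b}):{rng.exponential(0.5) + 0.05:.4f}")
    newick = f"({nodes[0]},{nodes[1]});"
    return tree_from_newick(newick)
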