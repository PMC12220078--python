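import numpy as np
import pandas as pd
import pytest

from rarescope.io_formats import parse_newick
from rarescope.synthetic_data import SimulationConfig, simulate_all


@pytest.fixture
def quartet_tree():
    """Symmetric 4-leaf tree: both cherries hang at RED 0.5."""
    return parse_newick("((A:1,B:1):1,(C:1,D:1):1);")


@pytest.fixture
def triplet_tree():
    return parse_newick("((A:1,B:1):1,C:2);")


@pytest.fixture(scope="session")
def sim_bundle():
    """One full synthetic dataset at the default study conditions."""
    return simulate_all(SimulationConfig(seed=11))


def random_tree_newick(rng, n_leaves):
    """A random binary tree with random branch lengths, as Newick text.

    Built by repeatedly joining two random subtrees — independent of the
    package's own Yule simulator so tree-based properties are checked on
    trees the implementation did not produce itself.
    """
    parts = [f"L{i}:{rng.uniform(0.1, 2.0):.4f}" for i in range(n_leaves)]
    while len(parts) > 1:
        i, j = rng.choice(len(parts), size=2, replace=False)
        a, b = parts[i], parts[j]
        merged = f"({a},{b}):{rng.uniform(0.1, 2.0):.4f}"
        parts = [p for k, p in enumerate(parts) if k not in (i, j)] + [merged]
    return parts[0][: parts[0].rfind(":")] + ";"
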