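import numpy as np
import pandas as pd
import pytest

import phylopathx as px
from phylopathx.synthdata import GeneratorSpec, simulate_tree


@pytest.fixture
def three_tip_tree():
    return px.read_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def balanced_four_tree():
    return px.read_newick("((A:1,B:1):1,(C:1,D:1):1);")


@pytest.fixture(scope="session")
def bd_tree_64():
    """64-tip birth-death tree shared across statistical tests."""
    return simulate_tree(GeneratorSpec(n_taxa=64, tree_model="birth_death", seed=64))


@pytest.fixture(scope="session")
def class_tree_68():
    """68 taxa in 35 families, the study-like classification tree shape."""
    return simulate_tree(GeneratorSpec(
        n_taxa=68, tree_model="classification_like", n_families=35, seed=68))


def random_tree_newick(rng: np.random.Generator, n_tips: int) -> str:
    """Random binary tree via recursive splitting, with random lengths."""
    labels = [f"t{i}" for i in range(n_tips)]

    def build(names):
        if len(names) == 1:
            return f"{names[0]}:{rng.uniform(0.1, 2.0):.4f}"
        k = int(rng.integers(1, len(names)))
        left, right = names[:k], names[k:]
        return (f"({build(left)},{build(right)}):{rng.uniform(0.1, 2.0):.4f}")

    return f"({build(labels[: n_tips // 2])},{build(labels[n_tips // 2:])});"


@pytest.fixture
def random_tree_factory():
    return random_tree_newick


def brownian_traits(tree, rng, n_traits=1):
    """Independent Brownian traits on a tree (test-side generator)."""
    cov = tree.brownian_covariance()
    L = np.linalg.cholesky(cov + 1e-10 * np.eye(len(cov)))
    data = {f"v{i}": L @ rng.standard_normal(len(cov)) for i in range(n_traits)}
    return pd.DataFrame(data, index=list(tree.tips))
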