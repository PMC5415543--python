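import numpy as np
import pytest

from phylotherm import load_surrogate_tree, load_trait_table, read_newick
from phylotherm.simulate import SimulationConfig, simulate_tree


@pytest.fixture(scope="session")
def trait_table():
    return load_trait_table()


@pytest.fixture(scope="session")
def surrogate_tree():
    return load_surrogate_tree()


@pytest.fixture()
def small_tree():
    return read_newick("((A:1,B:1):1,C:2);")


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


def random_yule_tree(n, seed):
    cfg = SimulationConfig(n_species=n, tree_model="pure_birth", seed=seed)
    return simulate_tree(cfg)
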