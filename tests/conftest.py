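import numpy as np
import pytest

from rnasaxs import synthetic as syn


@pytest.fixture(scope="session")
def two_helix_system():
    """Two-helix + internal-loop benchmark fixture (tree, native, lib, curve)."""
    return syn.benchmark_system(seed=42, copies=5)


@pytest.fixture(scope="session")
def stemloop_native():
    tree = syn.fixture_tree("(((((....)))))")
    return tree, syn.native_model(tree)


@pytest.fixture(scope="session")
def cloverleaf_tree():
    return syn.fixture_tree(syn.CLOVERLEAF_STRUCTURE)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
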