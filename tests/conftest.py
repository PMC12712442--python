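import numpy as np
import pytest

from frostdrought import simulate, trees


@pytest.fixture
def three_tip_tree():
    """((A:1,B:1):1,C:2); — MRCA(A,B) at depth 1, all tips at depth 2."""
    return trees.read_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def yule_tree():
    return simulate.sim_tree(40, seed=123)


@pytest.fixture
def yule_cov(yule_tree):
    return trees.vcv(yule_tree)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
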