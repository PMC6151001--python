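import numpy as np
import pytest

from pipalign import PIPContext, jc69, parse_newick


@pytest.fixture
def jc():
    """JC69 with deletion rate 1."""
    return jc69(1.0)


@pytest.fixture
def cherry():
    """Two-leaf tree with equal branches of 0.3."""
    return parse_newick("(A:0.3,B:0.3);")


@pytest.fixture
def three_leaf():
    return parse_newick("((A:0.2,B:0.4):0.3,C:0.25);")


@pytest.fixture
def cherry_ctx(cherry, jc):
    return PIPContext(cherry, jc, lam=1.0)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_trees(n_trees, rng, n_leaves_range=(2, 64), blen_range=(0.01, 2.0)):
    """Stream of random rooted binary trees for property checks."""
    from pipalign.simulate import random_tree

    lo, hi = n_leaves_range
    for _ in range(n_trees):
        n = int(rng.integers(lo, hi + 1))
        yield random_tree(n, rng, blen_range=blen_range)
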