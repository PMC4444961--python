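import numpy as np
import pytest

from socmir import make_published_fixture, parse_newick


@pytest.fixture(scope="session")
def fx():
    """The packaged published-facts fixture (matrix, tree, labels, panels)."""
    return make_published_fixture()


@pytest.fixture(scope="session")
def eight_leaf_tree():
    return parse_newick("(((A,B),(C,D)),((E,F),(G,H)));")


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
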