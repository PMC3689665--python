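import numpy as np
import pytest

from phyloconserve import parse_newick, simulate_yule_tree


@pytest.fixture
def balanced4():
    return parse_newick("((A:1,B:1):1,(C:1,D:1):1);")


@pytest.fixture
def star8():
    return parse_newick("(" + ",".join(f"t{i}:3" for i in range(8)) + ");")


@pytest.fixture
def yule_factory():
    """Seeded Yule-tree factory sharing one generator per test."""

    def make(n_tips, birth_rate=0.1, seed=0):
        return simulate_yule_tree(n_tips, birth_rate, seed)

    return make


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
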