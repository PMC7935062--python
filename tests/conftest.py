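import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from flpscape import mk, trees  # noqa: E402


@pytest.fixture(scope="session")
def balanced_tree():
    """((A:1,B:1):1,C:2); — three tips, equal depths."""
    return trees.read_newick("((A:1,B:1):1,C:2);", from_string=True)


@pytest.fixture(scope="session")
def six_tip_tree():
    """Two cherries plus two singletons, hand-checkable."""
    s = "(((A:0.3,B:0.4):0.5,C:0.8):0.2,((D:0.6,E:0.2):0.3,F:0.9):0.4);"
    return trees.read_newick(s, from_string=True)


def random_small_tree(rng, n_tips):
    seed = int(rng.integers(2 ** 31))
    return trees.simulate_yule_tree(n_tips, 1.0, seed)


def random_q(rng, kind="ARD"):
    if kind == "ER":
        return mk.build_rate_matrix("ER", [rng.uniform(0.2, 2.0)]).matrix
    if kind == "SYM":
        return mk.build_rate_matrix("SYM", rng.uniform(0.2, 2.0, 3)).matrix
    return mk.build_rate_matrix("ARD", rng.uniform(0.1, 2.0, 6)).matrix
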