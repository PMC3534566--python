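import warnings

import numpy as np
import pytest

from pyroclad.ctmc import MkModel
from pyroclad.synthetic_data import SimulationRecipe, make_fixture, simulate_tree
from pyroclad.treeio import parse_newick


@pytest.fixture
def tree3():
    return parse_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def tree5():
    return parse_newick("(((A:1,B:1):1,(C:1.5,D:1.5):0.5):1,E:3);")


@pytest.fixture(scope="session")
def tree80():
    return simulate_tree(SimulationRecipe(n_tips=80, crown_age=113.0, seed=42))


@pytest.fixture(scope="session")
def fixture_bundle():
    return make_fixture(seed=777)


@pytest.fixture(autouse=True)
def _quiet_invariant_warnings():
    # synthetic draws frequently produce invariant columns on tiny trees;
    # those warnings are themselves under test where they matter
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="invariant trait")
        warnings.filterwarnings("ignore", message="all tips ambiguous")
        yield


def random_mk_model(rng) -> MkModel:
    return MkModel(rng.uniform(0.01, 0.5), rng.uniform(0.01, 0.5))
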