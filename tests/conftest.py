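import numpy as np
import pytest

from wgtevol.loss_model import LossModelSpec
from wgtevol.pillar_hmm import HmmSpec, PillarSet
from wgtevol.trees import SpeciesTree, default_study_tree


@pytest.fixture(scope="session")
def study_tree():
    return default_study_tree()


@pytest.fixture(scope="session")
def two_tip_tree():
    return SpeciesTree.from_topology(("A", "B"),
                                     lengths={"A": 0.25, "B": 0.3, "root": 0.35})


@pytest.fixture(scope="session")
def three_tip_tree():
    return SpeciesTree.from_topology((("A", "B"), "C"),
                                     lengths={"A": 0.2, "B": 0.25, "C": 0.3,
                                              frozenset({"A", "B"}): 0.15,
                                              "root": 0.4})


@pytest.fixture(scope="session")
def g3_spec():
    return LossModelSpec.g3(sigma=0.8, fT=(0.6, 0.8, 1.0), fD=(0.5, 0.7, 1.0))


@pytest.fixture(scope="session")
def g3_root_spec():
    return LossModelSpec.g3_root(sigma=0.8, fT=(0.6, 0.8, 1.0), fD=(0.5, 0.7, 1.0),
                                 tau=1.0, beta12=0.3, beta13=0.3)


@pytest.fixture
def tiny_pillars():
    """Three pillars over two genomes with mixed patterns and one break."""
    patterns = np.array([[0, 0], [3, 5], [1, 2]])
    breaks = np.zeros((3, 2), dtype=bool)
    breaks[2, 1] = True
    return PillarSet(patterns, breaks, ("A", "B"))
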