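import numpy as np
import pytest
from skbio import DistanceMatrix

import coextdiv as cd


@pytest.fixture
def worked_dm():
    """Three species with d(A,B)=2, d(A,C)=d(B,C)=6."""
    return DistanceMatrix([[0, 2, 6], [2, 0, 6], [6, 6, 0]], ids=list("ABC"))


@pytest.fixture
def worked_tree(worked_dm):
    """UPGMA dendrogram of the worked distances: A,B merge at height 1,
    C joins at height 3; total branch length 7."""
    return cd.upgma(worked_dm)


@pytest.fixture
def worked_network():
    """2x2 network: pollinators X,Y over plants P,Q with counts
    [[3,1],[0,2]]."""
    return cd.QuantitativeNetwork(("X", "Y"), ("P", "Q"),
                                  np.array([[3, 1], [0, 2]]))


@pytest.fixture
def small_bundle():
    """A 10-plant / 15-pollinator synthetic community."""
    return cd.make_fixture(cd.SynthConfig(n_plants=10, n_pollinators=15,
                                          connectance=0.25, missing_rate=0.0,
                                          seed=11))
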