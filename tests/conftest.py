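import numpy as np
import pytest

from perturbmap import (
    GeneSignature,
    GeneUniverse,
    ReferenceProfile,
    ReferenceSet,
    database_from_profiles,
)


@pytest.fixture
def universe5():
    return GeneUniverse(("g1", "g2", "g3", "g4", "g5"))


@pytest.fixture
def profile5(universe5):
    # signed ranks {g1:+5, g2:-4, g3:+3, g4:-2, g5:+1}
    return ReferenceProfile(
        profile_id="p1",
        compound="cmpA",
        universe=universe5,
        ranks=np.array([5, -4, 3, -2, 1]),
    )


@pytest.fixture
def refset5(profile5):
    return ReferenceSet(compound="cmpA", profiles=(profile5,))


@pytest.fixture
def tiny_db(universe5, profile5):
    other = ReferenceProfile(
        profile_id="p2",
        compound="cmpB",
        universe=universe5,
        ranks=np.array([-1, 2, -3, 4, -5]),
    )
    return database_from_profiles([profile5, other])


@pytest.fixture
def sig_up_down():
    return GeneSignature((("g1", 1), ("g2", -1)), label="updown")
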