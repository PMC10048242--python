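import numpy as np
import pytest

from narnea.regulon import Regulon
from narnea.signature import DifferentialSignature, rank_sign_transform


@pytest.fixture
def sig5():
    """Five-gene micro signature used for all hand-computed examples."""
    return DifferentialSignature(
        np.array(["g1", "g2", "g3", "g4", "g5"], dtype=object),
        np.array([2.0, -1.0, 0.5, -0.2, 3.0]),
    )


@pytest.fixture
def rss5(sig5):
    return rank_sign_transform(sig5)


@pytest.fixture
def reg5():
    """Two-target regulon {g1, g5} with aw = 1, am = 0.5."""
    return Regulon(
        "r", np.array(["g1", "g5"], dtype=object), np.array([1.0, 1.0]), np.array([0.5, 0.5])
    )
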