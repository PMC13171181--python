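import random

import pytest

from singletrack import PenaltySet


@pytest.fixture
def affine():
    return PenaltySet.affine_default()


@pytest.fixture
def dual():
    return PenaltySet.dual_default()


@pytest.fixture
def worked(affine):
    """The worked instance: q=GCA vs t=GCCAA under (0, 4, 6, 2)."""
    return "GCA", "GCCAA", affine


def random_pair(rng: random.Random, max_len: int, min_len: int = 0):
    n = rng.randint(min_len, max_len)
    m = rng.randint(min_len, max_len)
    q = "".join(rng.choice("ACGT") for _ in range(n))
    t = "".join(rng.choice("ACGT") for _ in range(m))
    return q, t
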