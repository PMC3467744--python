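import random

import pytest
from hypothesis import settings

from seqforge.align import GapPenalty, SubstitutionMatrix

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def rng():
    return random.Random(20120809)


@pytest.fixture(scope="session")
def unit_matrix():
    """Match +1 / mismatch −1 over the four DNA bases."""
    return SubstitutionMatrix.match_mismatch(1, -1)


@pytest.fixture(scope="session")
def default_gap():
    return GapPenalty(-2, -1)


def random_dna(rng: random.Random, length: int) -> str:
    return "".join(rng.choice("ACGT") for _ in range(length))


def random_protein(rng: random.Random, length: int) -> str:
    return "".join(rng.choice("ARNDCQEGHILKMFPSTWYV") for _ in range(length))
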