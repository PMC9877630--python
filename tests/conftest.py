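import random

import pytest

import goldengate as gg
from goldengate.registry import SyntheticFdiSpec


@pytest.fixture(scope="session")
def bsai():
    return gg.get_enzyme("BsaI")


@pytest.fixture(scope="session")
def hindiii():
    return gg.get_enzyme("HindIII")


@pytest.fixture(scope="session")
def btr1_entry():
    return gg.get_vector("pK35BTR1")


@pytest.fixture(scope="session")
def btr2_entry():
    return gg.get_vector("pK35BTR2")


@pytest.fixture(scope="session")
def btr1_vector():
    return gg.mock_vector("pK35BTR1", seed=1)


@pytest.fixture(scope="session")
def btr2_vector():
    return gg.mock_vector("pK35BTR2", seed=2)


@pytest.fixture(scope="session")
def plain_fdi():
    """An FDI with no internal BsaI site."""
    return gg.generate_fdi(SyntheticFdiSpec(600, 0, seed=7))


@pytest.fixture
def rng():
    return random.Random(1234)


def random_dna(rng: random.Random, n: int) -> str:
    return "".join(rng.choices("ACGT", k=n))


def dna_without(rng: random.Random, n: int, motifs=("GGTCTC", "GAGACC")) -> str:
    while True:
        s = random_dna(rng, n)
        if not any(m in s for m in motifs):
            return s
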