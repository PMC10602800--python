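import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from corralign.matrices import (
    ALPHABET,
    PairSubstitutionMatrix400,
    SubstitutionMatrix20,
    load_named_matrix20,
)
from corralign.seqio import ProteinSequence


@pytest.fixture(scope="session")
def blosum62() -> SubstitutionMatrix20:
    return load_named_matrix20("blosum62")


@pytest.fixture
def simple_m20() -> SubstitutionMatrix20:
    """Match +2, mismatch -1."""
    scores = np.full((20, 20), -1.0)
    np.fill_diagonal(scores, 2.0)
    return SubstitutionMatrix20(scores=scores, name="simple")


@pytest.fixture
def zero_m400() -> PairSubstitutionMatrix400:
    return PairSubstitutionMatrix400(scores=np.zeros((400, 400)), name="zero")


def random_protein(rng: np.random.Generator, length: int, alphabet: str = ALPHABET, tag="r"):
    residues = "".join(rng.choice(list(alphabet), size=length))
    return ProteinSequence(id=f"{tag}{length}", residues=residues)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
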