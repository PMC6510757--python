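import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the _oracles helper

from stemloop.encode import DinucPropertyTable
from stemloop.hairpin import HairpinParams


@pytest.fixture(scope="session")
def table() -> DinucPropertyTable:
    return DinucPropertyTable.load_default()


@pytest.fixture
def default_params() -> HairpinParams:
    return HairpinParams()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)


def random_dna(rng: np.random.Generator, length: int, alphabet: str = "ACGT") -> str:
    return "".join(rng.choice(list(alphabet), size=length))
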