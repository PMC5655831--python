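import numpy as np
import pytest

from gpga.engine import SearchParams
from gpga.mapper import ExonQuery
from gpga.seqio import Sequence

BASES = "ACGT"


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, size=n))


def plant(background: str, insert: str, pos_1based: int) -> str:
    """Overwrite background with insert starting at a 1-based position."""
    i = pos_1based - 1
    return background[:i] + insert + background[i + len(insert):]


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def fast_params():
    """Small population for unit tests that only exercise the loop shape."""
    return SearchParams(pop_size=40, max_generations=400, stall_generations=50, seed=7)


@pytest.fixture
def planted_query(rng):
    """A 2 kb query with a unique 60 bp exon planted at position 701."""
    e = 60
    exon = random_dna(rng, e)
    q = plant(random_dna(rng, 2000), exon, 701)
    return Sequence("q", q), ExonQuery("g", 1, exon), 701
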