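import numpy as np
import pytest
from hypothesis import settings

from archamp.io import SeqRecord

settings.register_profile("ci", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("ci")

BASES = np.array(list("ACGT"))


def random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[rng.integers(0, 4, n)])


def mutate(seq: str, rng: np.random.Generator, rate: float) -> str:
    """Substitute each position with a different base with probability
    ``rate``."""
    arr = np.array(["ACGT".index(c) for c in seq])
    hit = rng.random(arr.size) < rate
    arr[hit] = (arr[hit] + rng.integers(1, 4, hit.sum())) % 4
    return "".join(BASES[arr])


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240916)


@pytest.fixture
def small_records():
    return [SeqRecord("a", "ACGTACGTAC", "first"),
            SeqRecord("b", "TTTTGGGGCC"),
            SeqRecord("c", "ACKGCTCAGT", "with degenerate K")]
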