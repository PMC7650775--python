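import numpy as np
import pytest

from baculokit import CircularGenome, generate_genome, maphgv_like_spec


def random_dna(rng, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), n))


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def synthetic_genome():
    """One study-like synthetic genome shared by read-only tests."""
    return generate_genome(maphgv_like_spec(seed=6))


@pytest.fixture
def small_circular(rng):
    return CircularGenome("small", random_dna(rng, 600))
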