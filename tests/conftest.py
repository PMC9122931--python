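import numpy as np
import pytest

from phageflux.io import ContigRecord
from phageflux.simulate import SimConfig, generate_community

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def random_dna(rng: np.random.Generator, n: int) -> str:
    return bytes(BASES[rng.integers(0, 4, n)]).decode()


def mutate(rng: np.random.Generator, seq: str, divergence: float) -> str:
    """Substitute an exact fraction of positions, each to a different base."""
    n = len(seq)
    positions = rng.choice(n, size=int(round(divergence * n)), replace=False)
    arr = list(seq)
    for p in positions:
        arr[p] = "ACGT".replace(arr[p], "")[rng.integers(0, 3)]
    return "".join(arr)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def small_community():
    """One small planted community shared by read-only tests."""
    return generate_community(SimConfig.small(seed=42))


def make_contig(rng, cid, n):
    return ContigRecord(cid, random_dna(rng, n))
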