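import numpy as np
import pytest

from clior.io import Read
from clior.synthetic import CommunitySpec, GenomeSpec, simulate_community


@pytest.fixture
def toy_reads():
    """Five short reads with known k-mer structure."""
    return [
        Read("a", "ACGTACGTACGT"),
        Read("b", "ACGTACGTACGA"),
        Read("c", "TTTTGGGGCCCC"),
        Read("d", "GGGGCCCCAAAA"),
        Read("e", "NNNNNNNNNNNN"),
    ]


@pytest.fixture(scope="session")
def small_community():
    """Error-free 2-species community: reads are exact genome substrings."""
    spec = CommunitySpec(
        genomes=[
            GenomeSpec("Escherichia_coli", "Escherichia", 20_000),
            GenomeSpec("Bacillus_cereus", "Bacillus", 20_000),
        ],
        abundances=[0.5, 0.5],
        n_reads=2_000,
        read_length=80,
        error_rate=0.0,
        seed=11,
    )
    return simulate_community(spec)


def random_reads(rng: np.random.Generator, n: int, length: int) -> list[Read]:
    """I.i.d. random reads (shared k-mers arise only by chance)."""
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    return [
        Read(f"rr{i}", bases[rng.integers(0, 4, size=length)].tobytes().decode())
        for i in range(n)
    ]
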