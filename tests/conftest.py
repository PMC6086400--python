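import numpy as np
import pytest

from persplice import Genome, SequenceRecord

BASES = np.array(list("ACGT"))


def random_seq(length: int, seed: int) -> str:
    rng = np.random.default_rng(seed)
    return "".join(BASES[rng.integers(0, 4, size=length)].tolist())


@pytest.fixture(scope="session")
def tiny_contig() -> SequenceRecord:
    return SequenceRecord("chr1", random_seq(2000, seed=42))


@pytest.fixture(scope="session")
def tiny_genome(tiny_contig) -> Genome:
    return Genome([tiny_contig])
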