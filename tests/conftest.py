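import numpy as np
import pytest

from prmscan.sequence_io import ProteinRecord


@pytest.fixture
def rng():
    return np.random.default_rng(20120415)


@pytest.fixture
def random_protein(rng):
    """Factory for random proteins over the full canonical alphabet."""

    alphabet = np.array(list("ACDEFGHIKLMNPQRSTVWY"))

    def make(length: int, pid: str = "rand") -> ProteinRecord:
        seq = "".join(rng.choice(alphabet, size=length))
        return ProteinRecord(id=pid, sequence=seq)

    return make
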