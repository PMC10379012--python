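import numpy as np
import pytest

from promgraph.io import PromoterDataset, SequenceRecord

BASES = "ACGT"


def random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, size=length))


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def tiny_dataset(rng):
    """12 labeled 20-bp windows, labels alternating, no planted structure."""
    records = [
        SequenceRecord(f"r{i}", random_sequence(rng, 20), i % 2) for i in range(12)
    ]
    return PromoterDataset(records, window_length=20, tss_index=15)
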