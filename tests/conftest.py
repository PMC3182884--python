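import numpy as np
import pytest

from ccvtyper.seqio import SequenceRecord
from ccvtyper.synthetic import SimulationSpec, simulate_dataset


@pytest.fixture(scope="session")
def planted_dataset():
    """Four well-separated groups of ten 1-kb sequences (the standard
    desk-scale genotyping fixture)."""
    return simulate_dataset(SimulationSpec(seed=42))


@pytest.fixture
def toy_records():
    return [
        SequenceRecord(id="s1", residues="ACGTACGT"),
        SequenceRecord(id="s2", residues="TTTTACGT"),
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
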