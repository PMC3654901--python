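import numpy as np
import pytest

from lcsclust.seqio import SequenceRecord


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def rec():
    """Shorthand constructor for anonymous sequence records."""

    def make(seq: str, name: str = "r") -> SequenceRecord:
        return SequenceRecord(name, seq)

    return make
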