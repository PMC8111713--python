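import numpy as np
import pytest

from ampliphase.align import AlignedRead
from ampliphase.seqio import Read, ReferenceSeq


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_ref():
    return ReferenceSeq("ref", "ACGTACGGTCAGCTTAGCATCCGATCGATTACGGCAT")


def random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


def perfect_alignment(read_id: str, bases: str, offset: int) -> AlignedRead:
    """An all-match alignment at the given offset."""
    return AlignedRead(
        read=Read(read_id, bases),
        ref_offset=offset,
        ops=[("match", len(bases), None)],
    )
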