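import numpy as np
import pytest

from rnapscreen.seqio import EnzymeRecord


@pytest.fixture
def rng():
    return np.random.default_rng(20240012)


@pytest.fixture
def small_library():
    """Three tiny hand-written protein records."""
    return [
        EnzymeRecord(accession="a1", protein_seq="MKVLAQSTYWDE"),
        EnzymeRecord(accession="a2", protein_seq="MKVLAQSTYWDF"),
        EnzymeRecord(accession="a3", protein_seq="GGHHPPRRCCNN"),
    ]


def random_seq(rng, length, alphabet="ACDEFGHIKLMNPQRSTVWY"):
    return "".join(rng.choice(list(alphabet), size=length))
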