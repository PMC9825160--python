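import pytest

from ribodesign import LibraryDefinition, PairingMap
from ribodesign.fixtures import make_ideal_helix


@pytest.fixture
def helix4():
    """4-bp ideal duplex, strand1 gcgu (A:2225-2228), strand2 its
    position-wise display partner cgca (B:2088-2091)."""
    return make_ideal_helix(
        4, "gcgu", sequence2="acgc", start_numbers=(2225, 2088)
    )


@pytest.fixture
def pairing44():
    return PairingMap.from_strands(4, 4)


@pytest.fixture
def h75_like_lib():
    """8-position anything-but-WT duplex library in the style of the helix
    75 center: strand1 positions 2225-2228 paired position-wise with
    strand2 positions 2088-2091."""
    wt1, wt2 = "gcgu", "cgca"  # 4 WC pairs position-wise
    positions = [("A", 2225 + i, wt1[i]) for i in range(4)] + [
        ("B", 2088 + i, wt2[i]) for i in range(4)
    ]
    return LibraryDefinition.anything_but_wt("H75", positions, strand_lengths=(4, 4))
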