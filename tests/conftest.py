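import pytest

from radsig.core import ProteinAlignment
from radsig.tree import parse_newick


@pytest.fixture
def small_alignment() -> ProteinAlignment:
    return ProteinAlignment(
        ["a", "b", "c", "d"],
        ["ARND", "ARNE", "GHIL", "GHIK"],
    )


@pytest.fixture
def supported_tree():
    return parse_newick("((A:1,B:1)90:1,C:2);")
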