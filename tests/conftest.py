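import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from kincomp.pedigree import Pedigree, PedigreeRecord


def _rec(ident, dam=None, sire=None, sex=None, unit=None):
    return PedigreeRecord(id=ident, dam=dam, sire=sire, sex=sex, birth_unit=unit)


@pytest.fixture
def mixed_trio_pedigree():
    """Focal A, paternal half-sibling H, maternal first cousin C.

    A and H share sire S; A's dam D1 and C's dam D3 are full sisters
    (daughters of GM x GF); H and C share no known ancestor.
    """
    return Pedigree(
        [
            _rec("GM", sex="F"),
            _rec("GF", sex="M"),
            _rec("D1", "GM", "GF", "F"),
            _rec("D3", "GM", "GF", "F"),
            _rec("D2", sex="F"),
            _rec("S", sex="M"),
            _rec("SC", sex="M"),
            _rec("A", "D1", "S", "F"),
            _rec("H", "D2", "S", "F"),
            _rec("C", "D3", "SC", "F"),
        ]
    )


@pytest.fixture
def cousin_trio_pedigree():
    """Three maternal first cousins: mothers are full sisters (GM x GF)."""
    return Pedigree(
        [
            _rec("GM", sex="F"),
            _rec("GF", sex="M"),
            _rec("M1", "GM", "GF", "F"),
            _rec("M2", "GM", "GF", "F"),
            _rec("M3", "GM", "GF", "F"),
            _rec("S1", sex="M"),
            _rec("S2", sex="M"),
            _rec("S3", sex="M"),
            _rec("C1", "M1", "S1", "F"),
            _rec("C2", "M2", "S2", "F"),
            _rec("C3", "M3", "S3", "F"),
        ]
    )


@pytest.fixture
def nuclear_pedigree():
    """Two founder parents with two offspring (full siblings)."""
    return Pedigree(
        [
            _rec("P1", sex="F"),
            _rec("P2", sex="M"),
            _rec("K1", "P1", "P2", "F"),
            _rec("K2", "P1", "P2", "M"),
        ]
    )
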