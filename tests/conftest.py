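import numpy as np
import pytest

from dcinbreed.genotypes import GenotypeTable


@pytest.fixture
def genepop_2digit(tmp_path):
    path = tmp_path / "two.gen"
    path.write_text(
        "toy panel\n"
        "locA\n"
        "locB\n"
        "Pop\n"
        "ind1 , 0101 0102\n"
        "ind2 , 0102 0000\n"
    )
    return path


@pytest.fixture
def genepop_3digit(tmp_path):
    path = tmp_path / "three.gen"
    path.write_text(
        "toy panel\n"
        "locA\n"
        "Pop\n"
        "ind1 , 001002\n"
        "ind2 , 001001\n"
    )
    return path


@pytest.fixture
def hwe_table():
    """One locus, genotypes {AA, AB, BB, AB}: p_A = 0.5."""
    return GenotypeTable(
        ["i1", "i2", "i3", "i4"],
        ["L1"],
        [[("A", "A")], [("A", "B")], [("B", "B")], [("A", "B")]],
    )


@pytest.fixture
def rng():
    return np.random.default_rng(0)
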