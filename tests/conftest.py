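import numpy as np
import pytest

from polykaryo.seqio import (
    MultipleAlignment,
    Region,
    RegionMap,
    SampleRow,
    SampleSheet,
)


@pytest.fixture
def toy_alignment() -> MultipleAlignment:
    #            123456789012345678901234567890
    return MultipleAlignment(
        (
            ("s1", "ACGTACGTACGTACGTACGTACGTACGTAC"),
            ("s2", "ACGTACGTACGTACGTACGTACGTACGTAC"),
            ("s3", "ACATACGTACGTACGAACGTACGTACGTAC"),
            ("s4", "ACATACGTAC--ACGAACGTACGTACGTAC"),
        )
    )


@pytest.fixture
def toy_regions() -> RegionMap:
    return RegionMap(
        (Region(1, 10, "exon"), Region(11, 20, "intron"), Region(21, 30, "exon"))
    )


@pytest.fixture
def single_region():
    def make(length: int, label: str = "exon") -> RegionMap:
        return RegionMap((Region(1, length, label),))

    return make


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def make_sheet(rows):
    return SampleSheet(tuple(SampleRow(*r) for r in rows))


@pytest.fixture
def sheet_factory():
    return make_sheet
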