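import numpy as np
import pytest

from phylodelta.alignment import (ConcatenatedAlignment, LocusAlignment,
                                  PartitionMap, SampleMetadata,
                                  SequenceRecord)


def make_concat(rows: dict[str, str], partitions=None) -> ConcatenatedAlignment:
    """Concatenated alignment from {taxon: sequence}, single partition by
    default."""
    taxa = list(rows)
    matrix = np.array([list(s) for s in rows.values()], dtype="S1")
    L = matrix.shape[1]
    pmap = PartitionMap(partitions or [("l1", 0, L)])
    return ConcatenatedAlignment(taxa, matrix, pmap)


def make_locus(locus_id: str, rows: dict[str, str]) -> LocusAlignment:
    return LocusAlignment(locus_id,
                          [SequenceRecord(t, s) for t, s in rows.items()])


@pytest.fixture
def toy_metadata():
    return {
        "A": SampleMetadata("A", "modern", 2010),
        "B": SampleMetadata("B", "modern", 2005),
        "C": SampleMetadata("C", "historical", 1920),
        "D": SampleMetadata("D", "historical", 1900),
    }


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
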