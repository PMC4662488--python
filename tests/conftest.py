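import numpy as np
import pytest

from sncrna.core import AlignmentRecord, CountMatrix, GenomicFeature


@pytest.fixture
def small_matrix():
    """4 features x 4 samples, equal library sizes, hand-set counts."""
    counts = np.array(
        [
            [100, 120, 90, 110],
            [10, 12, 30, 28],
            [0, 0, 0, 0],
            [500, 480, 510, 490],
        ]
    )
    samples = ["T1", "T2", "N1", "N2"]
    return CountMatrix(
        feature_ids=["fA", "fB", "fZero", "fC"],
        sample_ids=samples,
        counts=counts,
        group={"T1": "case", "T2": "case", "N1": "control", "N2": "control"},
        lib_sizes={s: 1_000_000 for s in samples},
    )


def make_feature(fid="f1", cls="miRNA", chrom="chr1", start=1000, end=1070, strand="+"):
    return GenomicFeature(fid, cls, chrom, start, end, strand, fid)


def make_read(rid="r1", chrom="chr1", start=1000, end=1022, strand="+", mult=1):
    return AlignmentRecord(rid, chrom, start, end, strand, mult)


@pytest.fixture
def feature_factory():
    return make_feature


@pytest.fixture
def read_factory():
    return make_read
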