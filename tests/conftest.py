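import numpy as np
import pytest

from regdriver.intervals import GenomicInterval, PeakSet


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def random_peakset(rng, n, label="P", chroms=("chr1", "chr2"), max_pos=10_000):
    ivs = []
    for _ in range(n):
        chrom = chroms[rng.integers(0, len(chroms))]
        start = int(rng.integers(0, max_pos - 1))
        end = int(rng.integers(start + 1, min(start + 200, max_pos) + 1))
        ivs.append(GenomicInterval(chrom, start, end))
    return PeakSet(label, ivs)


@pytest.fixture
def make_peakset():
    return random_peakset
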