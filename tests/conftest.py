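import numpy as np
import pytest

from k9balance.genome import GenomicInterval, TERecord


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_intervals(rng, n, chrom="chr1", max_coord=10_000):
    """Random small-coordinate intervals for per-base oracle checks."""
    out = []
    for _ in range(n):
        a, b = sorted(rng.integers(0, max_coord, size=2))
        out.append(GenomicInterval(chrom, int(a), int(b) + 1))
    return out


def per_base_set(intervals):
    """Per-base membership oracle: the set of covered base positions."""
    covered = set()
    for iv in intervals:
        covered.update(range(iv.start, iv.end))
    return covered


def make_tes(intervals, superfamily="other"):
    return [
        TERecord(id=f"te{i}", interval=iv, superfamily=superfamily)
        for i, iv in enumerate(intervals)
    ]
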