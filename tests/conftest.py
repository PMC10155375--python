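import numpy as np
import pytest

from capdepth import CoverageProfile, GenomicInterval, IntervalSet


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def flat_profile():
    """Constant 100x depth over a single 10,000-bp target."""
    targets = IntervalSet([GenomicInterval("chr1", 0, 10_000)], merged=True)
    return CoverageProfile(targets, np.full(10_000, 100, dtype=np.int64))


def random_interval_set(rng, n, max_coord=10_000, chroms=("chrA", "chrB")):
    out = []
    for _ in range(n):
        chrom = chroms[rng.integers(len(chroms))]
        start = int(rng.integers(0, max_coord - 1))
        end = int(rng.integers(start + 1, min(start + 500, max_coord) + 1))
        out.append(GenomicInterval(chrom, start, end))
    return IntervalSet(out)


def base_set(s: IntervalSet):
    """Brute-force per-base membership oracle."""
    return {(iv.chrom, b) for iv in s for b in range(iv.start, iv.end)}
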