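"""Shared fixtures and independent oracles for the test suite."""

import numpy as np
import pytest

from panacr.intervals import GenomicInterval, IntervalSet


def bitmap(s: IntervalSet, chrom: str, length: int) -> np.ndarray:
    """Per-bp boolean-mask oracle for one contig."""
    mask = np.zeros(length, dtype=bool)
    for iv in s:
        if iv.chrom == chrom:
            mask[iv.start:iv.end] = True
    return mask


def mask_to_intervals(mask: np.ndarray, chrom: str) -> IntervalSet:
    """Connected runs of a boolean mask as intervals."""
    padded = np.concatenate(([False], mask, [False]))
    diff = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1)
    return IntervalSet(
        GenomicInterval(chrom, int(a), int(b)) for a, b in zip(starts, ends)
    )


def random_interval_set(rng, n, chroms=("chr1", "chr2"), length=100_000, max_len=500):
    out = []
    for _ in range(n):
        chrom = chroms[int(rng.integers(len(chroms)))]
        start = int(rng.integers(0, length - max_len))
        out.append(
            GenomicInterval(chrom, start, start + int(rng.integers(1, max_len + 1)))
        )
    return IntervalSet(out)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
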