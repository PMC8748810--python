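"""Shared fixtures and independent per-base oracles for interval operations.

The oracles deliberately use the dumbest possible representation — a boolean
array over every base of a toy chromosome — so they share no code with the
sweep-line implementations they check.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from g4scape.intervals import GenomicInterval, IntervalSet

settings.register_profile("ci", derandomize=True, max_examples=100, deadline=None)
settings.load_profile("ci")

TOY_CHROM_LEN = 10_000


@pytest.fixture
def toy_assembly() -> dict[str, int]:
    return {"chr1": TOY_CHROM_LEN}


def iset(pairs, assembly, name="s", chrom="chr1") -> IntervalSet:
    return IntervalSet(
        [GenomicInterval(chrom, s, e) for s, e in pairs], assembly, name
    )


def per_base_coverage(sets: list[IntervalSet], chrom: str, length: int) -> np.ndarray:
    """Number of sets covering each base (each set counted at most once/base)."""
    depth = np.zeros(length, dtype=int)
    for s in sets:
        covered = np.zeros(length, dtype=bool)
        for iv in s:
            if iv.chrom == chrom:
                covered[iv.start : iv.end] = True
        depth += covered
    return depth


def runs_of_true(mask: np.ndarray) -> list[tuple[int, int]]:
    """Run-length encode a boolean array into half-open (start, end) pairs."""
    out = []
    start = None
    for i, v in enumerate(mask):
        if v and start is None:
            start = i
        elif not v and start is not None:
            out.append((start, i))
            start = None
    if start is not None:
        out.append((start, len(mask)))
    return out


def random_interval_pairs(rng: np.random.Generator, n: int, length: int,
                          max_width: int = 400) -> list[tuple[int, int]]:
    starts = rng.integers(0, length - 1, size=n)
    widths = rng.integers(1, max_width, size=n)
    return [(int(s), int(min(length, s + w))) for s, w in zip(starts, widths)]
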