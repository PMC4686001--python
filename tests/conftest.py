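"""Shared fixtures and brute-force oracles for the test suite.

The oracles here are deliberately naive (per-base sets, nested loops) so they
stay independent of the sweep/bisect implementations they check.
"""

from __future__ import annotations

import numpy as np
import pytest

from chipcord.intervals import GenomicInterval, Peak


def make_peak(chrom: str, start: int, end: int, name: str = ".") -> Peak:
    return Peak(interval=GenomicInterval(chrom, start, end), name=name)


def make_peaks(tuples) -> list[Peak]:
    return [make_peak(*t) for t in tuples]


def random_intervals(
    rng: np.random.Generator,
    n: int,
    chroms=("chrA", "chrB"),
    max_start: int = 5_000,
    max_len: int = 300,
) -> list[GenomicInterval]:
    out = []
    for _ in range(n):
        chrom = chroms[rng.integers(len(chroms))]
        start = int(rng.integers(0, max_start))
        length = int(rng.integers(1, max_len))
        out.append(GenomicInterval(chrom, start, start + length))
    return out


def random_peaks(rng: np.random.Generator, n: int, **kw) -> list[Peak]:
    return [Peak(interval=iv) for iv in random_intervals(rng, n, **kw)]


# ---------------------------------------------------------------------------
# per-base / nested-loop oracles


def covered_bases(intervals) -> set[tuple[str, int]]:
    """Every (chrom, base) covered by at least one interval."""
    bases: set[tuple[str, int]] = set()
    for iv in intervals:
        for b in range(iv.start, iv.end):
            bases.add((iv.chrom, b))
    return bases


def bases_to_intervals(bases: set[tuple[str, int]]) -> list[GenomicInterval]:
    """Merge a base set back into maximal runs (the per-base merge oracle)."""
    out = []
    by_chrom: dict[str, list[int]] = {}
    for chrom, b in bases:
        by_chrom.setdefault(chrom, []).append(b)
    for chrom in sorted(by_chrom):
        positions = sorted(by_chrom[chrom])
        run_start = positions[0]
        prev = positions[0]
        for b in positions[1:]:
            if b != prev + 1:
                out.append(GenomicInterval(chrom, run_start, prev + 1))
                run_start = b
            prev = b
        out.append(GenomicInterval(chrom, run_start, prev + 1))
    return out


def brute_overlaps(a: GenomicInterval, b: GenomicInterval) -> bool:
    return bool(covered_bases([a]) & covered_bases([b]))


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)
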