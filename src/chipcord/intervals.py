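"""Genomic interval model and narrowPeak/BED I/O.

Coordinates are 0-based half-open throughout (BED convention): an interval
``[start, end)`` covers ``end - start`` bases.  Two intervals overlap iff they
share at least one base, i.e. ``max(starts) < min(ends)`` on the same
chromosome — the minimal-overlap-of-one-base-pair rule that every downstream
comparison in this package uses.  Strand is ignored in all overlap arithmetic
(ChIP peaks are unstranded).

Peaks within one list are kept as read from the file: they are not
deduplicated or pre-merged, so row counts match the source peak caller output.
"""

from __future__ import annotations

import gzip
from bisect import bisect_right
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "GenomicInterval",
    "Peak",
    "Experiment",
    "Condition",
    "PeakPartition",
    "overlaps",
    "overlap_length",
    "merge_intervals",
    "merge_regions",
    "intersect_regions",
    "common_regions",
    "partition_condition",
    "read_narrowpeak",
    "write_narrowpeak",
]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic interval ``chrom:[start, end)``."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"end must exceed start, got [{self.start}, {self.end})"
            )

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass(frozen=True)
class Peak:
    """One narrowPeak record.

    ``signal``, ``neg_log10_p`` and ``neg_log10_q`` may be ``None`` when the
    source file had fewer than the full ten columns; ``summit_offset`` is the
    summit position relative to ``start``, or -1 when not called.
    """

    interval: GenomicInterval
    name: str = "."
    score: int = 0
    strand: str = "."
    signal: float | None = None
    neg_log10_p: float | None = None
    neg_log10_q: float | None = None
    summit_offset: int = -1

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")
        if self.summit_offset >= len(self.interval):
            raise ValueError(
                f"summit offset {self.summit_offset} outside peak of length "
                f"{len(self.interval)}"
            )

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def start(self) -> int:
        return self.interval.start

    @property
    def end(self) -> int:
        return self.interval.end


def _sort_key(p: Peak) -> tuple[str, int, int]:
    return (p.interval.chrom, p.interval.start, p.interval.end)


@dataclass
class Experiment:
    """A single ChIP-seq experiment: a peak list plus metadata."""

    id: str
    condition_id: str = ""
    lab: str = ""
    antibody: str = ""
    peaks: list[Peak] = field(default_factory=list)
    fragment_source: str | None = None

    def __post_init__(self) -> None:
        self.peaks = sorted(self.peaks, key=_sort_key)

    @property
    def n_peaks(self) -> int:
        return len(self.peaks)


@dataclass
class Condition:
    """A (factor, cell line, treatment) triple with 2-5 replicate experiments."""

    id: str
    factor: str = ""
    cell_line: str = ""
    treatment: str = ""
    experiments: list[Experiment] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [e.id for e in self.experiments]
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate experiment ids in condition {self.id}")

    def require_replicates(self) -> None:
        if len(self.experiments) < 2:
            raise ValueError(
                f"condition {self.id} has {len(self.experiments)} experiment(s); "
                "replicate analysis needs at least 2"
            )


@dataclass
class PeakPartition:
    """Per-experiment split of a replicated condition's peaks.

    common: this experiment's peaks that overlap >=1 peak of *every* other
    replicate.  sample_specific: peaks overlapping no peak of any other
    replicate.  undetected: merged regions covered by other replicates' peaks
    but free of any peak of this experiment.  With >=3 replicates, peaks
    overlapping some-but-not-all other replicates fall in neither common nor
    sample_specific.
    """

    experiment_id: str
    common: list[Peak]
    sample_specific: list[Peak]
    undetected: list[GenomicInterval]


# ---------------------------------------------------------------------------
# interval arithmetic


def overlaps(a: GenomicInterval, b: GenomicInterval) -> bool:
    """True iff the intervals share at least one base."""
    return a.chrom == b.chrom and max(a.start, b.start) < min(a.end, b.end)


def overlap_length(a: GenomicInterval, b: GenomicInterval) -> int:
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def merge_intervals(ivs: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Minimal sorted set of disjoint intervals covering the input.

    Intervals are merged only when they share >=1 base; half-open abutment
    ([a,b) next to [b,c)) stays two intervals.
    """
    ivs = sorted(ivs, key=lambda i: (i.chrom, i.start, i.end))
    out: list[GenomicInterval] = []
    for iv in ivs:
        if out and out[-1].chrom == iv.chrom and iv.start < out[-1].end:
            if iv.end > out[-1].end:
                out[-1] = GenomicInterval(iv.chrom, out[-1].start, iv.end)
        else:
            out.append(iv)
    return out


def _peak_intervals(peaks: Sequence[Peak]) -> list[GenomicInterval]:
    return [p.interval for p in peaks]


def merge_regions(*peak_lists: Sequence[Peak]) -> list[GenomicInterval]:
    """Disjoint union of every peak across all input lists."""
    ivs: list[GenomicInterval] = []
    for pl in peak_lists:
        ivs.extend(_peak_intervals(pl))
    return merge_intervals(ivs)


def intersect_regions(
    a: Sequence[GenomicInterval], b: Sequence[GenomicInterval]
) -> list[GenomicInterval]:
    """Genomic intersection of two sorted disjoint interval sets."""
    by_chrom_b: dict[str, list[GenomicInterval]] = {}
    for iv in b:
        by_chrom_b.setdefault(iv.chrom, []).append(iv)
    out: list[GenomicInterval] = []
    for iv in a:
        for other in by_chrom_b.get(iv.chrom, ()):
            s = max(iv.start, other.start)
            e = min(iv.end, other.end)
            if s < e:
                out.append(GenomicInterval(iv.chrom, s, e))
    return sorted(out, key=lambda i: (i.chrom, i.start))


def common_regions(*peak_lists: Sequence[Peak]) -> list[GenomicInterval]:
    """Maximal segments covered by >=1 peak in *every* input list.

    Computed as the iterated pairwise intersection of each list's merged
    coverage; the result is sorted and non-overlapping.
    """
    if len(peak_lists) < 2:
        raise ValueError("common_regions needs at least 2 peak lists")
    current = merge_intervals(_peak_intervals(peak_lists[0]))
    for pl in peak_lists[1:]:
        current = intersect_regions(current, merge_intervals(_peak_intervals(pl)))
        if not current:
            break
    return current


class _RegionIndex:
    """Overlap queries against a merged (sorted, disjoint) interval set."""

    def __init__(self, merged: Sequence[GenomicInterval]):
        self._starts: dict[str, list[int]] = {}
        self._ends: dict[str, list[int]] = {}
        for iv in merged:
            self._starts.setdefault(iv.chrom, []).append(iv.start)
            self._ends.setdefault(iv.chrom, []).append(iv.end)

    def overlaps(self, iv: GenomicInterval) -> bool:
        starts = self._starts.get(iv.chrom)
        if not starts:
            return False
        # candidate: the rightmost region starting before iv.end
        i = bisect_right(starts, iv.end - 1) - 1
        return i >= 0 and self._ends[iv.chrom][i] > iv.start


def partition_condition(cond: Condition) -> list[PeakPartition]:
    """Split each replicate's peaks into common / sample-specific / undetected."""
    cond.require_replicates()
    merged_by_exp = {
        e.id: merge_intervals(_peak_intervals(e.peaks)) for e in cond.experiments
    }
    indexes = {eid: _RegionIndex(m) for eid, m in merged_by_exp.items()}

    partitions: list[PeakPartition] = []
    for e in cond.experiments:
        others = [o for o in cond.experiments if o.id != e.id]
        common: list[Peak] = []
        specific: list[Peak] = []
        for p in e.peaks:
            hits = sum(indexes[o.id].overlaps(p.interval) for o in others)
            if hits == len(others):
                common.append(p)
            elif hits == 0:
                specific.append(p)
        own_index = indexes[e.id]
        union_others = merge_intervals(
            iv for o in others for iv in merged_by_exp[o.id]
        )
        undetected = [iv for iv in union_others if not own_index.overlaps(iv)]
        partitions.append(
            PeakPartition(
                experiment_id=e.id,
                common=common,
                sample_specific=specific,
                undetected=undetected,
            )
        )
    return partitions


# ---------------------------------------------------------------------------
# narrowPeak / BED I/O


class NarrowPeakParseError(ValueError):
    pass


def _open_text(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def _parse_line(line: str, lineno: int) -> Peak:
    fields = line.rstrip("\n").split("\t")
    if not 6 <= len(fields) <= 10:
        raise NarrowPeakParseError(
            f"line {lineno}: expected 6-10 tab-separated columns, got {len(fields)}"
        )
    try:
        chrom = fields[0]
        start = int(fields[1])
        end = int(fields[2])
        name = fields[3]
        score = int(float(fields[4]))
        strand = fields[5]
        signal = float(fields[6]) if len(fields) > 6 else None
        p = float(fields[7]) if len(fields) > 7 else None
        q = float(fields[8]) if len(fields) > 8 else None
        summit = int(fields[9]) if len(fields) > 9 else -1
    except (ValueError, IndexError) as exc:
        raise NarrowPeakParseError(f"line {lineno}: {exc}") from exc
    if end <= start:
        raise NarrowPeakParseError(
            f"line {lineno}: end ({end}) must exceed start ({start})"
        )
    # narrowPeak uses -1 for missing p/q; keep None for absent columns
    if p is not None and p < 0:
        p = None
    if q is not None and q < 0:
        q = None
    return Peak(
        interval=GenomicInterval(chrom, start, end),
        name=name,
        score=score,
        strand=strand,
        signal=signal,
        neg_log10_p=p,
        neg_log10_q=q,
        summit_offset=summit,
    )


def read_narrowpeak(path: str | Path) -> list[Peak]:
    """Read a narrowPeak (BED6+4) or BED6 file; gzip transparently supported.

    Returns peaks sorted by (chrom, start); missing optional columns become
    ``None`` (signal/p/q) or -1 (summit).
    """
    peaks: list[Peak] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            peaks.append(_parse_line(line, lineno))
    return sorted(peaks, key=_sort_key)


def _fmt_float(x: float | None, missing: str = "-1") -> str:
    if x is None:
        return missing
    return f"{x:g}"


def write_narrowpeak(peaks: Iterable[Peak], path: str | Path) -> None:
    """Write peaks as 10-column narrowPeak (missing p/q written as -1)."""
    with _open_text(path, "wt") as fh:
        for p in sorted(peaks, key=_sort_key):
            fh.write(
                "\t".join(
                    [
                        p.chrom,
                        str(p.start),
                        str(p.end),
                        p.name,
                        str(p.score),
                        p.strand,
                        _fmt_float(p.signal, "0"),
                        _fmt_float(p.neg_log10_p),
                        _fmt_float(p.neg_log10_q),
                        str(p.summit_offset),
                    ]
                )
                + "\n"
            )


def total_bp(ivs: Iterable[GenomicInterval]) -> int:
    return sum(len(iv) for iv in ivs)
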