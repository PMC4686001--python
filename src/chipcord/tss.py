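"""Closest-TSS annotation with strand-aware signed distances.

The TSS of a transcript on the + strand is its start coordinate; on the -
strand it is ``end - 1`` (0-based).  A peak's distance to its nearest TSS is
measured from the peak midpoint and signed by gene orientation: positive when
the midpoint lies downstream (3') of the TSS, negative upstream.  Ties on
absolute distance are broken toward the downstream (positive) TSS.

Promoter-proximal binding is characteristic of many transcription regulators,
so the distance distribution per peak set (common / sample-specific /
undetected) is a cheap biological-plausibility check when arbitrating between
discordant replicates.
"""

from __future__ import annotations

from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .intervals import GenomicInterval, Peak, PeakPartition

__all__ = [
    "TranscriptRecord",
    "TSSIndex",
    "build_tss_index",
    "read_transcripts_gtf",
    "nearest_tss_distance",
    "tss_summary",
]


@dataclass(frozen=True)
class TranscriptRecord:
    """Minimal transcript: half-open interval plus strand and id."""

    chrom: str
    start: int
    end: int
    strand: str
    transcript_id: str

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1


@dataclass
class TSSIndex:
    """Per-chromosome sorted TSS positions with the strands/ids at each.

    Transcripts sharing a TSS are collapsed onto one position entry.
    """

    positions: dict[str, list[int]] = field(default_factory=dict)
    entries: dict[str, list[list[tuple[str, str]]]] = field(default_factory=dict)
    n_skipped: int = 0

    def chromosomes(self) -> list[str]:
        return sorted(self.positions)

    @property
    def n_sites(self) -> int:
        return sum(len(v) for v in self.positions.values())

    def all_sites(self) -> Iterable[tuple[str, int, str]]:
        """Yield (chrom, position, strand) over every collapsed entry."""
        for chrom, pos_list in self.positions.items():
            for pos, entry in zip(pos_list, self.entries[chrom]):
                for strand, _tid in entry:
                    yield chrom, pos, strand


def build_tss_index(transcripts: Iterable[TranscriptRecord]) -> TSSIndex:
    """Collapse transcripts to unique TSS positions per chromosome."""
    by_pos: dict[str, dict[int, list[tuple[str, str]]]] = {}
    skipped = 0
    for t in transcripts:
        if t.strand not in ("+", "-"):
            skipped += 1
            continue
        by_pos.setdefault(t.chrom, {}).setdefault(t.tss, []).append(
            (t.strand, t.transcript_id)
        )
    idx = TSSIndex(n_skipped=skipped)
    for chrom, mapping in by_pos.items():
        pos_sorted = sorted(mapping)
        idx.positions[chrom] = pos_sorted
        idx.entries[chrom] = [mapping[p] for p in pos_sorted]
    return idx


def read_transcripts_gtf(path: str | Path) -> list[TranscriptRecord]:
    """Read transcript features from a GTF file.

    GTF coordinates are 1-based closed; they are converted to 0-based
    half-open on read.  Only ``transcript`` feature lines are used.
    """
    records: list[TranscriptRecord] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9 or f[2] != "transcript":
                continue
            attrs = f[8]
            tid = ""
            for part in attrs.split(";"):
                part = part.strip()
                if part.startswith("transcript_id"):
                    tid = part.split(" ", 1)[1].strip().strip('"')
                    break
            records.append(
                TranscriptRecord(
                    chrom=f[0],
                    start=int(f[3]) - 1,
                    end=int(f[4]),
                    strand=f[6],
                    transcript_id=tid,
                )
            )
    return records


def _signed(midpoint: int, tss_pos: int, strand: str) -> int:
    # positive downstream of the TSS in gene orientation
    return midpoint - tss_pos if strand == "+" else tss_pos - midpoint


def nearest_tss_distance(
    peak: Peak | GenomicInterval, idx: TSSIndex
) -> int | None:
    """Signed distance from the peak midpoint to the nearest TSS.

    Nearest by absolute distance; ties (including a TSS carrying both
    strands) resolve toward the downstream, i.e. positive, sign.  Returns
    ``None`` when the peak's chromosome has no TSS.
    """
    iv = peak.interval if isinstance(peak, Peak) else peak
    positions = idx.positions.get(iv.chrom)
    if not positions:
        return None
    mid = iv.midpoint
    i = bisect_left(positions, mid)
    candidates: list[int] = []
    if i < len(positions):
        candidates.append(i)
    if i > 0:
        candidates.append(i - 1)
    best_abs = min(abs(positions[j] - mid) for j in candidates)
    signed_options: list[int] = []
    for j in candidates:
        if abs(positions[j] - mid) != best_abs:
            continue
        for strand, _tid in idx.entries[iv.chrom][j]:
            signed_options.append(_signed(mid, positions[j], strand))
    return max(signed_options)  # ties toward downstream (positive)


def _overlaps_tss(iv: GenomicInterval, idx: TSSIndex) -> bool:
    positions = idx.positions.get(iv.chrom)
    if not positions:
        return False
    return bisect_left(positions, iv.start) < bisect_right(positions, iv.end - 1)


_HIST_EDGES = np.array([0, 1, 10, 100, 1_000, 10_000, 100_000, 1_000_000, np.inf])


def _summarize_one(
    intervals: Sequence[GenomicInterval], idx: TSSIndex
) -> dict:
    distances: list[int] = []
    n_missing = 0
    n_overlap = 0
    for iv in intervals:
        d = nearest_tss_distance(iv, idx)
        if d is None:
            n_missing += 1
            continue
        distances.append(d)
        if _overlaps_tss(iv, idx):
            n_overlap += 1
    if not distances:
        return {
            "n": len(intervals),
            "n_missing": n_missing,
            "median_abs_distance": float("nan"),
            "fraction_tss_overlap": float("nan"),
            "fraction_downstream": float("nan"),
            "histogram": np.zeros(len(_HIST_EDGES) - 1, dtype=int),
        }
    arr = np.array(distances)
    hist, _ = np.histogram(np.abs(arr), bins=_HIST_EDGES)
    return {
        "n": len(intervals),
        "n_missing": n_missing,
        "median_abs_distance": float(np.median(np.abs(arr))),
        "fraction_tss_overlap": n_overlap / len(arr),
        "fraction_downstream": float(np.mean(arr > 0)),
        "histogram": hist,
    }


def tss_summary(
    peaks: Sequence[Peak] | PeakPartition, idx: TSSIndex
) -> dict[str, dict]:
    """Distance-distribution summaries per peak set.

    Accepts a plain peak list (summarized under the key ``"all"``) or a
    :class:`PeakPartition` (keys common / sample_specific / undetected).
    Each summary carries median absolute distance, the fraction of peaks
    containing a TSS, the fraction strictly downstream, and a histogram of
    absolute distances over decade bins.
    """
    if isinstance(peaks, PeakPartition):
        sets: dict[str, list[GenomicInterval]] = {
            "common": [p.interval for p in peaks.common],
            "sample_specific": [p.interval for p in peaks.sample_specific],
            "undetected": list(peaks.undetected),
        }
    else:
        sets = {"all": [p.interval for p in peaks]}
    return {name: _summarize_one(ivs, idx) for name, ivs in sets.items()}
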