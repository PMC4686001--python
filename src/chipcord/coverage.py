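"""Fragment counting, FPKM/FRiP enrichment metrics and coverage profiles.

Each sequenced read is represented by a single point: its 5' position shifted
towards the fragment centre by ``shift`` base pairs (+shift on the + strand,
-shift on the - strand; default 150 bp, a typical ChIP fragment half-length).
No read extension is applied — one global shift keeps fragment counting
consistent between the coverage profiles here and the MA-normalization module.

FPKM (fragments per kilobase per million mapped fragments) normalizes a
region's fragment count for both region length and library size, so
enrichment is comparable across experiments of different depth.  FRiP is the
fraction of all fragments falling inside the (merged) peak regions — a
signal-to-noise proxy.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .intervals import (
    Condition,
    GenomicInterval,
    Peak,
    PeakPartition,
    merge_regions,
    partition_condition,
)

__all__ = [
    "FragmentSet",
    "CoverageProfile",
    "read_fragments_bed",
    "count_fragments",
    "peak_fpkm",
    "frip",
    "coverage_profile",
    "depth_vs_peaks",
]

DEFAULT_SHIFT = 150

PEAK_SET_NAMES = ("common", "sample_specific", "undetected")


@dataclass
class FragmentSet:
    """Shifted 5'-position index for one experiment's fragments.

    ``positions`` maps chromosome -> sorted array of shifted positions.
    ``library_size`` is the total number of fragments (assumed already
    deduplicated / uniquely aligned).
    """

    experiment_id: str
    positions: dict[str, np.ndarray]
    shift: int = DEFAULT_SHIFT

    def __post_init__(self) -> None:
        if self.shift < 0:
            raise ValueError("shift must be >= 0")
        self.positions = {
            c: np.sort(np.asarray(p, dtype=np.int64))
            for c, p in self.positions.items()
        }

    @property
    def library_size(self) -> int:
        return sum(len(p) for p in self.positions.values())

    @classmethod
    def from_reads(
        cls,
        experiment_id: str,
        reads: Iterable[tuple[str, int, str]],
        shift: int = DEFAULT_SHIFT,
    ) -> "FragmentSet":
        """Build from (chrom, 5'-position, strand) triples, applying the shift."""
        by_chrom: dict[str, list[int]] = {}
        for chrom, pos5, strand in reads:
            shifted = pos5 + shift if strand != "-" else pos5 - shift
            by_chrom.setdefault(chrom, []).append(max(shifted, 0))
        return cls(experiment_id, {c: np.array(v) for c, v in by_chrom.items()}, shift)


def read_fragments_bed(
    path: str | Path, experiment_id: str, shift: int = DEFAULT_SHIFT
) -> FragmentSet:
    """Load reads from a BED6 file; the 5' end is start on +, end-1 on -."""
    reads: list[tuple[str, int, str]] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split("\t")
            chrom, start, end = f[0], int(f[1]), int(f[2])
            strand = f[5] if len(f) > 5 else "+"
            pos5 = start if strand != "-" else end - 1
            reads.append((chrom, pos5, strand))
    return FragmentSet.from_reads(experiment_id, reads, shift)


def count_fragments(region: GenomicInterval, fragments: FragmentSet) -> int:
    """Number of shifted fragment positions inside ``[start, end)``."""
    pos = fragments.positions.get(region.chrom)
    if pos is None:
        return 0
    lo = np.searchsorted(pos, region.start, side="left")
    hi = np.searchsorted(pos, region.end, side="left")
    return int(hi - lo)


def peak_fpkm(region: GenomicInterval, fragments: FragmentSet) -> float:
    """FPKM = count / (length_kb * library_millions)."""
    lib = fragments.library_size
    if lib == 0:
        raise ValueError("library_size must be positive for FPKM")
    length = len(region)
    if length == 0:
        raise ValueError("zero-length region")
    n = count_fragments(region, fragments)
    return n / ((length / 1e3) * (lib / 1e6))


def frip(peaks: Sequence[Peak], fragments: FragmentSet) -> float:
    """Fraction of fragments whose shifted position lies in the merged peaks."""
    lib = fragments.library_size
    if lib == 0:
        raise ValueError("library_size must be positive for FRiP")
    merged = merge_regions(peaks)
    inside = sum(count_fragments(iv, fragments) for iv in merged)
    return inside / lib


@dataclass
class CoverageProfile:
    """Mean FPKM per bin around peak midpoints, one curve per peak set.

    Curves are NaN vectors when the corresponding peak set is empty; ``n_peaks``
    records how many windows were averaged.  ``clipped`` counts windows that
    extended below position 0.
    """

    window_half_width: int
    bin_width: int
    curves: dict[str, np.ndarray]
    n_peaks: dict[str, int]
    clipped: int = 0

    @property
    def n_bins(self) -> int:
        return 2 * self.window_half_width // self.bin_width

    def bin_centers(self) -> np.ndarray:
        w, b = self.window_half_width, self.bin_width
        return np.arange(-w + b / 2, w, b)


def _profile_one_set(
    midpoints: list[tuple[str, int]],
    fragments: FragmentSet,
    whw: int,
    bin_width: int,
) -> tuple[np.ndarray, int]:
    n_bins = 2 * whw // bin_width
    lib_millions = fragments.library_size / 1e6
    bin_kb = bin_width / 1e3
    total = np.zeros(n_bins)
    clipped = 0
    for chrom, mid in midpoints:
        if mid - whw < 0:
            clipped += 1
        pos = fragments.positions.get(chrom)
        if pos is None:
            continue
        edges = mid - whw + bin_width * np.arange(n_bins + 1)
        idx = np.searchsorted(pos, edges, side="left")
        total += np.diff(idx)
    mean_counts = total / len(midpoints)
    return mean_counts / (bin_kb * lib_millions), clipped


def coverage_profile(
    partition: PeakPartition,
    fragments: FragmentSet,
    window_half_width: int = 2000,
    bin_width: int = 10,
) -> CoverageProfile:
    """Mean coverage (FPKM) around common / sample-specific / undetected peaks.

    Windows are centred on peak midpoints (undetected regions have no native
    summit, so midpoints are used uniformly).  Empty peak sets yield NaN
    curves rather than zeros, so absence of peaks is distinguishable from
    absence of signal.
    """
    if 2 * window_half_width % bin_width != 0:
        raise ValueError("bin_width must evenly divide the window")
    sets: dict[str, list[tuple[str, int]]] = {
        "common": [(p.chrom, p.interval.midpoint) for p in partition.common],
        "sample_specific": [
            (p.chrom, p.interval.midpoint) for p in partition.sample_specific
        ],
        "undetected": [(iv.chrom, iv.midpoint) for iv in partition.undetected],
    }
    n_bins = 2 * window_half_width // bin_width
    curves: dict[str, np.ndarray] = {}
    n_peaks: dict[str, int] = {}
    clipped = 0
    for name, mids in sets.items():
        n_peaks[name] = len(mids)
        if not mids:
            curves[name] = np.full(n_bins, np.nan)
            continue
        curves[name], c = _profile_one_set(
            mids, fragments, window_half_width, bin_width
        )
        clipped += c
    return CoverageProfile(window_half_width, bin_width, curves, n_peaks, clipped)


def depth_vs_peaks(
    cond: Condition, fragment_sets: Mapping[str, FragmentSet]
) -> dict:
    """Diagnose whether peak counts track sequencing depth or ChIP enrichment.

    Returns per-experiment (n_peaks, library_size, median common-peak FPKM)
    plus, for 2 replicates, booleans ``depth_concordant`` (the deeper library
    has more peaks) and ``enrichment_concordant`` (the higher-enrichment
    experiment has more peaks); for >=3 replicates, the sign of the Pearson
    correlation for both pairings.
    """
    cond.require_replicates()
    partitions = {p.experiment_id: p for p in partition_condition(cond)}
    per_exp = []
    missing = []
    for e in cond.experiments:
        fs = fragment_sets.get(e.id)
        if fs is None:
            missing.append(e.id)
            per_exp.append(
                {"experiment_id": e.id, "n_peaks": e.n_peaks,
                 "library_size": None, "median_common_fpkm": None}
            )
            continue
        common = partitions[e.id].common
        med = (
            float(np.median([peak_fpkm(p.interval, fs) for p in common]))
            if common
            else float("nan")
        )
        per_exp.append(
            {
                "experiment_id": e.id,
                "n_peaks": e.n_peaks,
                "library_size": fs.library_size,
                "median_common_fpkm": med,
            }
        )
    record: dict = {"condition_id": cond.id, "per_experiment": per_exp}
    if missing:
        record["missing_fragments"] = missing
        return record

    n_peaks = np.array([r["n_peaks"] for r in per_exp], dtype=float)
    libs = np.array([r["library_size"] for r in per_exp], dtype=float)
    fpkms = np.array([r["median_common_fpkm"] for r in per_exp], dtype=float)
    if len(per_exp) == 2:
        record["depth_concordant"] = bool(
            (libs[0] - libs[1]) * (n_peaks[0] - n_peaks[1]) > 0
        )
        record["enrichment_concordant"] = bool(
            (fpkms[0] - fpkms[1]) * (n_peaks[0] - n_peaks[1]) > 0
        )
    else:
        with np.errstate(invalid="ignore"):
            record["depth_corr_sign"] = int(np.sign(np.corrcoef(libs, n_peaks)[0, 1]))
            record["enrichment_corr_sign"] = int(
                np.sign(np.corrcoef(fpkms, n_peaks)[0, 1])
            )
    return record
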