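"""Three-way replicate-concordance classification and merge recommendation.

A condition (same factor, cell line, treatment; 2-5 replicate experiments) is
labelled from peak-list overlap:

* **similar** — in every replicate, at least 50% of peaks overlap the common
  peak regions (regions covered by every replicate).
* **sensitive** — not similar, but the largest peak list is at least twice the
  size of the smallest and more than 70% of the smallest list overlaps the
  common regions.  This pattern arises when replicates differ mainly in ChIP
  efficiency: one experiment trades false negatives for false positives.
* **dissimilar** — everything else.

Fractions are computed over peak counts, not base pairs.  All three cut-offs
are exposed in :class:`ClassThresholds`; boundary semantics follow the rules'
wording literally: >=0.50 and >=2x are inclusive, >0.70 is strict.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .intervals import (
    Condition,
    GenomicInterval,
    Peak,
    _RegionIndex,
    common_regions,
    merge_regions,
)

__all__ = [
    "ExperimentOverlap",
    "OverlapSummary",
    "ClassThresholds",
    "overlap_summary",
    "classify_condition",
    "summarize_dataset",
    "recommend_peak_list",
    "SIMILAR",
    "SENSITIVE",
    "DISSIMILAR",
]

SIMILAR = "similar"
SENSITIVE = "sensitive"
DISSIMILAR = "dissimilar"
LABELS = (SIMILAR, SENSITIVE, DISSIMILAR)


@dataclass(frozen=True)
class ExperimentOverlap:
    experiment_id: str
    n_peaks: int
    n_overlapping_common: int

    @property
    def fraction(self) -> float:
        return self.n_overlapping_common / self.n_peaks


@dataclass(frozen=True)
class OverlapSummary:
    condition_id: str
    per_experiment: tuple[ExperimentOverlap, ...]
    n_common_regions: int


@dataclass(frozen=True)
class ClassThresholds:
    """Decision cut-offs; defaults are the published rule."""

    similar_min_fraction: float = 0.50
    sensitive_size_ratio: float = 2.0
    sensitive_min_small_fraction: float = 0.70

    def __post_init__(self) -> None:
        if not 0 < self.similar_min_fraction <= 1:
            raise ValueError("similar_min_fraction must be in (0, 1]")
        if self.sensitive_size_ratio <= 0:
            raise ValueError("sensitive_size_ratio must be positive")
        if not 0 < self.sensitive_min_small_fraction <= 1:
            raise ValueError("sensitive_min_small_fraction must be in (0, 1]")


def overlap_summary(cond: Condition) -> OverlapSummary:
    """Per-replicate fraction of peaks overlapping the common peak regions."""
    cond.require_replicates()
    for e in cond.experiments:
        if not e.peaks:
            raise ValueError(
                f"experiment {e.id} in condition {cond.id} has an empty peak list"
            )
    regions = common_regions(*(e.peaks for e in cond.experiments))
    index = _RegionIndex(regions)
    per_exp = tuple(
        ExperimentOverlap(
            experiment_id=e.id,
            n_peaks=e.n_peaks,
            n_overlapping_common=sum(index.overlaps(p.interval) for p in e.peaks),
        )
        for e in cond.experiments
    )
    return OverlapSummary(
        condition_id=cond.id, per_experiment=per_exp, n_common_regions=len(regions)
    )


def classify_condition(
    summary: OverlapSummary, thresholds: ClassThresholds | None = None
) -> str:
    """Map an overlap summary to similar / sensitive / dissimilar.

    With more than two replicates the sensitivity rule compares the largest
    against the smallest list and tests the smallest list's common fraction —
    the most conservative single reading of the pairwise rule.
    """
    t = thresholds or ClassThresholds()
    if len(summary.per_experiment) < 2:
        raise ValueError("classification needs a summary over >=2 experiments")
    fractions = [e.fraction for e in summary.per_experiment]
    if all(f >= t.similar_min_fraction for f in fractions):
        return SIMILAR
    sizes = [e.n_peaks for e in summary.per_experiment]
    smallest = min(summary.per_experiment, key=lambda e: e.n_peaks)
    if (
        max(sizes) >= t.sensitive_size_ratio * min(sizes)
        and smallest.fraction > t.sensitive_min_small_fraction
    ):
        return SENSITIVE
    return DISSIMILAR


def summarize_dataset(
    conditions: list[Condition], thresholds: ClassThresholds | None = None
) -> pd.DataFrame:
    """Classify every condition; one row per condition.

    Columns: condition_id, label, n_experiments, n_common_regions,
    experiment_ids / n_peaks / fractions (comma-joined per-replicate values).
    Aggregate counts per label are available via ``df['label'].value_counts()``.
    """
    ids = [c.id for c in conditions]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate condition ids in dataset")
    rows = []
    for cond in conditions:
        s = overlap_summary(cond)
        label = classify_condition(s, thresholds)
        rows.append(
            {
                "condition_id": cond.id,
                "label": label,
                "n_experiments": len(s.per_experiment),
                "n_common_regions": s.n_common_regions,
                "experiment_ids": ",".join(e.experiment_id for e in s.per_experiment),
                "n_peaks": ",".join(str(e.n_peaks) for e in s.per_experiment),
                "fractions": ",".join(f"{e.fraction:.4f}" for e in s.per_experiment),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "condition_id",
            "label",
            "n_experiments",
            "n_common_regions",
            "experiment_ids",
            "n_peaks",
            "fractions",
        ],
    )


@dataclass
class PeakListRecommendation:
    regions: list[GenomicInterval]
    strategy: str
    warning: str | None = None


def recommend_peak_list(
    cond: Condition, label: str, preferred_replicate: str | None = None
) -> PeakListRecommendation:
    """Merged-list recommendation given the condition's concordance label.

    Similar and sensitive conditions get the union of replicate peaks.  For a
    dissimilar condition, external evidence (clustering, TSS proximity, motif)
    may name a preferred replicate whose peaks are returned verbatim;
    otherwise the conservative intersection is returned with a warning.
    """
    if label in (SIMILAR, SENSITIVE):
        return PeakListRecommendation(
            regions=merge_regions(*(e.peaks for e in cond.experiments)),
            strategy="union",
        )
    if preferred_replicate is not None:
        match = [e for e in cond.experiments if e.id == preferred_replicate]
        if not match:
            raise ValueError(
                f"override replicate {preferred_replicate!r} not in condition {cond.id}"
            )
        return PeakListRecommendation(
            regions=[p.interval for p in match[0].peaks],
            strategy=f"replicate:{preferred_replicate}",
        )
    return PeakListRecommendation(
        regions=common_regions(*(e.peaks for e in cond.experiments)),
        strategy="intersection",
        warning=(
            "dissimilar condition without an externally preferred replicate; "
            "returning conservative intersection"
        ),
    )
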