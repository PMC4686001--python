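"""Binary occupancy matrix, Pearson correlation and hierarchical clustering.

Experiments are compared genome-wide on a binary regions x experiments
matrix: the region universe is the merged union of all peaks, and entry
(r, e) is 1 when experiment e has at least one peak overlapping region r.
Pearson correlation between binary columns (the phi coefficient) measures
co-occupancy; agglomerative clustering on distance d = 1 - r groups
experiments by shared binding repertoire.  A replicate of uncertain quality
can then be arbitrated by which known experiments it clusters with.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .intervals import Experiment, GenomicInterval, _RegionIndex, merge_regions

__all__ = [
    "OccupancyMatrix",
    "build_occupancy",
    "correlation_matrix",
    "hier_cluster",
    "nearest_neighbors",
    "dendrogram_to_newick",
]


@dataclass
class OccupancyMatrix:
    """Regions x experiments binary matrix (values in {0, 1})."""

    regions: list[GenomicInterval]
    experiments: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int8)
        if self.values.shape != (len(self.regions), len(self.experiments)):
            raise ValueError("matrix shape does not match regions x experiments")

    def column(self, experiment_id: str) -> np.ndarray:
        return self.values[:, self.experiments.index(experiment_id)]


def build_occupancy(experiments: list[Experiment]) -> OccupancyMatrix:
    """Merged-universe occupancy: entry 1 iff the experiment covers the region.

    Experiments are ordered lexicographically by id so that all downstream
    results (correlations, dendrograms, tie-breaks) are order-independent.
    """
    if len(experiments) < 2:
        raise ValueError("occupancy matrix needs >=2 experiments")
    experiments = sorted(experiments, key=lambda e: e.id)
    universe = merge_regions(*(e.peaks for e in experiments))
    values = np.zeros((len(universe), len(experiments)), dtype=np.int8)
    for j, e in enumerate(experiments):
        idx = _RegionIndex(merge_regions(e.peaks))
        for i, region in enumerate(universe):
            values[i, j] = idx.overlaps(region)
    return OccupancyMatrix(
        regions=universe, experiments=[e.id for e in experiments], values=values
    )


def correlation_matrix(m: OccupancyMatrix) -> np.ndarray:
    """Pearson r between binary columns; NaN (with a warning) for constant ones."""
    if len(m.experiments) < 2:
        raise ValueError("need >=2 columns")
    X = m.values.astype(float)
    sd = X.std(axis=0)
    constant = sd == 0
    if constant.any():
        names = [e for e, c in zip(m.experiments, constant) if c]
        warnings.warn(f"constant occupancy column(s): {names}; correlations are NaN")
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(X, rowvar=False)
    np.fill_diagonal(corr, 1.0)
    corr[constant, :] = np.nan
    corr[:, constant] = np.nan
    return corr


def hier_cluster(
    corr: np.ndarray,
    labels: list[str],
    method: str = "complete",
    strict: bool = True,
) -> tuple[np.ndarray, list[str]]:
    """Agglomerative clustering on d = 1 - r.

    Returns the scipy linkage matrix and the leaf order (labels).  Labels are
    sorted lexicographically before clustering so equal-distance merges
    resolve deterministically.  NaN correlations abort in strict mode;
    otherwise they are replaced by the worst observed distance.
    """
    corr = np.asarray(corr, dtype=float)
    order = np.argsort(labels)
    labels_sorted = [labels[i] for i in order]
    corr = corr[np.ix_(order, order)]
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    if np.isnan(dist).any():
        if strict:
            raise ValueError("correlation matrix contains missing values")
        warnings.warn("missing correlations replaced by max observed distance")
        dist = np.where(np.isnan(dist), np.nanmax(dist), dist)
    Z = hierarchy.linkage(squareform(dist, checks=False), method=method)
    leaf_idx = hierarchy.leaves_list(Z)
    return Z, [labels_sorted[i] for i in leaf_idx]


def nearest_neighbors(
    corr: np.ndarray, labels: list[str], query: str, k: int = 5
) -> list[tuple[str, float]]:
    """Top-k experiments by correlation with the query, self excluded.

    Ties in r are broken lexicographically; if k exceeds the number of other
    experiments, all of them are returned.
    """
    if query not in labels:
        raise KeyError(f"unknown experiment id {query!r}")
    qi = labels.index(query)
    others = [
        (labels[j], float(corr[qi, j])) for j in range(len(labels)) if j != qi
    ]
    others.sort(key=lambda t: (-(t[1] if not np.isnan(t[1]) else -np.inf), t[0]))
    return others[: min(k, len(others))]


def dendrogram_to_newick(Z: np.ndarray, labels: list[str]) -> str:
    """Serialize a scipy linkage matrix as a Newick tree with branch lengths."""
    n = len(labels)
    heights = {i: 0.0 for i in range(n)}

    def node_str(i: int) -> str:
        if i < n:
            return labels[i]
        left, right, height, _ = Z[i - n]
        left, right = int(left), int(right)
        bl_l = height - heights[left]
        bl_r = height - heights[right]
        return f"({node_str(left)}:{bl_l:.6g},{node_str(right)}:{bl_r:.6g})"

    for row_i, (_, _, h, _) in enumerate(Z):
        heights[n + row_i] = float(h)
    return node_str(n + len(Z) - 1) + ";"
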