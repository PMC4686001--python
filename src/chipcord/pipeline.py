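"""Manifest-driven orchestration of the full per-condition analysis.

A manifest TSV (columns: experiment_id, condition_id, factor, cell_line,
treatment, lab, antibody, peak_path, fragment_path) groups experiments into
conditions.  Each condition is classified from peak overlap; stages needing
optional inputs (fragments, annotation) are skipped and flagged in lenient
mode rather than aborting, since peak lists are typically available for all
experiments while alignments are a heavyweight optional input.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import clustering, concordance, coverage, madiff, tss
from .intervals import Condition, Experiment, read_narrowpeak, partition_condition

__all__ = ["PipelineConfig", "read_manifest", "run_pipeline", "write_report"]

log = logging.getLogger("chipcord")

MANIFEST_COLUMNS = [
    "experiment_id",
    "condition_id",
    "factor",
    "cell_line",
    "treatment",
    "lab",
    "antibody",
    "peak_path",
    "fragment_path",
]


@dataclass
class PipelineConfig:
    thresholds: concordance.ClassThresholds = field(
        default_factory=concordance.ClassThresholds
    )
    shift: int = coverage.DEFAULT_SHIFT
    window_half_width: int = 2000
    bin_width: int = 10
    ma_pseudocount: float = madiff.DEFAULT_PSEUDOCOUNT
    ma_alpha: float = madiff.DEFAULT_ALPHA
    linkage: str = "complete"
    strict: bool = False
    annotation_path: str | None = None
    output_dir: str = "chipcord_out"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        thr = raw.pop("thresholds", None)
        cfg = cls(**raw)
        if thr:
            cfg.thresholds = concordance.ClassThresholds(**thr)
        return cfg


def read_manifest(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"manifest missing column(s): {missing}")
    if df["experiment_id"].duplicated().any():
        raise ValueError("duplicate experiment_id in manifest")
    return df


def _resolve(path: str, base: Path | None) -> str:
    if path and base is not None and not Path(path).is_absolute():
        return str(base / path)
    return path


def _load_conditions(
    manifest: pd.DataFrame, base_dir: Path | None = None
) -> list[Condition]:
    """Relative manifest paths are resolved against the manifest's directory."""
    conditions = []
    for cid, grp in manifest.groupby("condition_id", sort=True):
        exps = []
        for _, row in grp.iterrows():
            peak_path = _resolve(row["peak_path"], base_dir)
            if not peak_path or not Path(peak_path).exists():
                raise FileNotFoundError(
                    f"manifest row for experiment {row['experiment_id']}: "
                    f"peak file not found: {peak_path!r}"
                )
            exps.append(
                Experiment(
                    id=row["experiment_id"],
                    condition_id=cid,
                    lab=row["lab"],
                    antibody=row["antibody"],
                    peaks=read_narrowpeak(peak_path),
                    fragment_source=_resolve(row["fragment_path"], base_dir) or None,
                )
            )
        conditions.append(
            Condition(
                id=cid,
                factor=grp["factor"].iloc[0],
                cell_line=grp["cell_line"].iloc[0],
                treatment=grp["treatment"].iloc[0],
                experiments=exps,
            )
        )
    return conditions


def run_pipeline(manifest_path: str | Path, config: PipelineConfig | None = None) -> dict:
    """Run classification, coverage, TSS, MA and clustering stages.

    Returns a results dict; use :func:`write_report` to serialize it.
    """
    config = config or PipelineConfig()
    t0 = time.time()
    manifest = read_manifest(manifest_path)
    conditions = _load_conditions(manifest, Path(manifest_path).parent)
    log.info("loaded %d conditions / %d experiments", len(conditions), len(manifest))

    tss_index = None
    if config.annotation_path:
        tss_index = tss.build_tss_index(
            tss.read_transcripts_gtf(config.annotation_path)
        )

    classification = concordance.summarize_dataset(conditions, config.thresholds)
    label_by_cond = dict(zip(classification["condition_id"], classification["label"]))

    per_condition: dict[str, dict] = {}
    for cond in sorted(conditions, key=lambda c: c.id):
        entry: dict = {"label": label_by_cond[cond.id], "skipped": []}
        partitions = partition_condition(cond)
        entry["partition_stats"] = {
            p.experiment_id: {
                "common": len(p.common),
                "sample_specific": len(p.sample_specific),
                "undetected": len(p.undetected),
            }
            for p in partitions
        }
        fsets = {}
        for e in cond.experiments:
            if e.fragment_source:
                fsets[e.id] = coverage.read_fragments_bed(
                    e.fragment_source, e.id, config.shift
                )
        if len(fsets) == len(cond.experiments):
            entry["profiles"] = {
                p.experiment_id: coverage.coverage_profile(
                    p,
                    fsets[p.experiment_id],
                    config.window_half_width,
                    config.bin_width,
                )
                for p in partitions
            }
            entry["depth_vs_peaks"] = coverage.depth_vs_peaks(cond, fsets)
        else:
            entry["skipped"].append("coverage (missing fragment data)")

        if tss_index is not None:
            entry["tss"] = {
                p.experiment_id: tss.tss_summary(p, tss_index) for p in partitions
            }
        else:
            entry["skipped"].append("tss (no annotation)")

        if len(cond.experiments) == 2 and len(fsets) == 2:
            try:
                _table, ma_summary = madiff.run_ma_analysis(
                    cond, fsets, config.ma_pseudocount, config.ma_alpha
                )
                entry["ma"] = ma_summary
            except ValueError as exc:
                entry["skipped"].append(f"ma ({exc})")
        else:
            entry["skipped"].append("ma (needs exactly 2 replicates with fragments)")

        rec = concordance.recommend_peak_list(cond, label_by_cond[cond.id])
        entry["recommendation"] = {
            "strategy": rec.strategy,
            "n_regions": len(rec.regions),
            "warning": rec.warning,
        }
        per_condition[cond.id] = entry

    all_experiments = [e for c in conditions for e in c.experiments]
    occupancy = clustering.build_occupancy(all_experiments)
    corr = clustering.correlation_matrix(occupancy)
    Z, leaf_order = clustering.hier_cluster(
        corr, occupancy.experiments, method=config.linkage, strict=config.strict
    )
    newick = clustering.dendrogram_to_newick(
        Z, sorted(occupancy.experiments)
    )

    results = {
        "config": {
            "thresholds": asdict(config.thresholds),
            "shift": config.shift,
            "window_half_width": config.window_half_width,
            "bin_width": config.bin_width,
            "ma_pseudocount": config.ma_pseudocount,
            "ma_alpha": config.ma_alpha,
            "linkage": config.linkage,
        },
        "classification": classification,
        "class_counts": classification["label"].value_counts().to_dict(),
        "per_condition": per_condition,
        "correlation": corr,
        "experiment_order": occupancy.experiments,
        "leaf_order": leaf_order,
        "newick": newick,
        "elapsed_s": time.time() - t0,
    }
    log.info("pipeline done in %.1fs", results["elapsed_s"])
    return results


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, coverage.CoverageProfile):
        return {
            name: [None if np.isnan(v) else round(float(v), 6) for v in curve]
            for name, curve in obj.curves.items()
        }
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def write_report(results: dict, out_dir: str | Path) -> dict[str, Path]:
    """Serialize pipeline results: TSV table, JSON summary, Newick dendrogram."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}

    tsv = out / "classification.tsv"
    results["classification"].to_csv(tsv, sep="\t", index=False)
    paths["classification"] = tsv

    corr_path = out / "correlation.tsv"
    pd.DataFrame(
        results["correlation"],
        index=results["experiment_order"],
        columns=results["experiment_order"],
    ).to_csv(corr_path, sep="\t")
    paths["correlation"] = corr_path

    nwk = out / "dendrogram.nwk"
    nwk.write_text(results["newick"] + "\n")
    paths["dendrogram"] = nwk

    summary = {
        "config": results["config"],
        "class_counts": results["class_counts"],
        "per_condition": _jsonable(results["per_condition"]),
        "leaf_order": results["leaf_order"],
    }
    js = out / "summary.json"
    js.write_text(json.dumps(summary, indent=2, sort_keys=True))
    paths["summary"] = js
    return paths
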