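"""Seeded generator of replicate ChIP-seq conditions with known ground truth.

The generator emulates the data a replicate-concordance analysis consumes:

* **True binding sites** are placed without overlap on a small genome.  Site
  strengths are heterogeneous (log-normal multipliers on the enrichment
  fold), and each replicate *detects* the top-scoring fraction of its
  detectable sites, where the score is the shared site strength plus
  replicate-specific noise — so detection is signal-coupled, as in real peak
  calling: sites missed by one replicate are on average weaker, yet still
  enriched.  A condition engineered to be *dissimilar* instead draws
  replicates' detectable sites from partially disjoint subsets (the
  ``site_overlap`` parameter), mimicking replicates that genuinely bind
  different repertoires (e.g. different antibody isoform specificity).
* **Peaks** are detected sites with jittered boundaries, plus false peaks
  scattered as a Poisson process — replicates can thus differ through false
  positives, false negatives, or repertoire, the mechanisms that produce the
  similar / sensitive / dissimilar phenotypes.
* **Fragments** are a uniform background plus ``enrichment_fold`` extra mass
  at *true* sites (not at called peaks), so sites a replicate failed to call
  still carry real signal — the feature that makes coverage at "undetected"
  peaks intermediate rather than zero.  Each fragment is emitted as a
  strand-random 5' read position offset by the global read shift, so
  shifting reads back by the same amount recovers fragment centres.

All randomness flows from a single integer seed through
``numpy.random.default_rng``; identical seeds give identical output bytes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .intervals import (
    Condition,
    Experiment,
    GenomicInterval,
    Peak,
    write_narrowpeak,
)
from .coverage import DEFAULT_SHIFT, FragmentSet
from .tss import TranscriptRecord, TSSIndex, build_tss_index

__all__ = [
    "GenomeSpec",
    "ReplicateSpec",
    "ConditionSpec",
    "GroundTruth",
    "generate_condition",
    "generate_tss",
    "generate_dataset",
    "recovery_specs",
    "DEFAULT_GENOME",
]


@dataclass(frozen=True)
class GenomeSpec:
    """Chromosome names and lengths of the simulated genome."""

    chromosomes: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        if any(length <= 0 for _, length in self.chromosomes):
            raise ValueError("chromosome lengths must be positive")

    @property
    def total_length(self) -> int:
        return sum(length for _, length in self.chromosomes)


DEFAULT_GENOME = GenomeSpec((("chrS1", 1_500_000), ("chrS2", 1_000_000)))


@dataclass(frozen=True)
class ReplicateSpec:
    """Per-replicate detection and sequencing behaviour.

    detection_sensitivity: probability of calling each detectable true site.
    false_peak_rate: expected spurious peaks per megabase.
    boundary_jitter: maximal +/- shift of each peak edge (bp).
    enrichment_fold: fragment density at true sites relative to background.
    library_size: total fragments to draw (0 = no fragment data).
    """

    detection_sensitivity: float = 0.9
    false_peak_rate: float = 2.0
    boundary_jitter: int = 20
    enrichment_fold: float = 5.0
    library_size: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.detection_sensitivity <= 1:
            raise ValueError("detection_sensitivity must be in [0, 1]")
        if self.false_peak_rate < 0 or self.boundary_jitter < 0:
            raise ValueError("rates and jitter must be >= 0")
        if self.enrichment_fold <= 1:
            raise ValueError("enrichment_fold must exceed 1")


@dataclass(frozen=True)
class ConditionSpec:
    """Full recipe for one replicated condition."""

    condition_id: str
    replicates: tuple[ReplicateSpec, ...]
    n_true_sites: int = 300
    site_width: tuple[int, int] = (200, 400)
    background_rate: float = 0.01  # fragments per bp, sets default library size
    site_overlap: float = 1.0  # fraction of sites detectable by all replicates
    strength_sd: float = 0.5  # sd of log site-strength multipliers
    detection_noise: float = 1.0  # per-replicate noise on the detection score
    promoter_bias: float = 0.0  # fraction of sites centred on sampled TSSs
    intended_class: str | None = None
    shift: int = DEFAULT_SHIFT
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.replicates) < 2:
            raise ValueError("a condition needs >=2 replicates")
        if not 0 < self.site_overlap <= 1:
            raise ValueError("site_overlap must be in (0, 1]")
        if not 0 <= self.promoter_bias <= 1:
            raise ValueError("promoter_bias must be in [0, 1]")


@dataclass
class GroundTruth:
    """What the generator knows that the analysis must rediscover."""

    condition_id: str
    true_sites: list[GenomicInterval]
    site_strength: np.ndarray  # per-site enrichment multiplier (mean 1)
    detectable: dict[str, np.ndarray]  # replicate id -> bool per site
    detected: dict[str, np.ndarray]  # replicate id -> bool per site
    intended_class: str | None


def _place_sites(
    genome: GenomeSpec,
    n: int,
    width_range: tuple[int, int],
    jitter: int,
    rng: np.random.Generator,
    tss_sites: Sequence[tuple[str, int, str]] | None = None,
    promoter_bias: float = 0.0,
) -> list[GenomicInterval]:
    """Non-overlapping site placement via slot sampling.

    The genome is cut into slots wide enough to hold any site plus jitter; a
    random subset of slots gets one site each, guaranteeing disjointness.
    With ``promoter_bias``, that fraction of sites is centred on sampled TSS
    positions instead (overlaps with slot sites are tolerated there: promoter
    placement is about TSS proximity, not disjointness guarantees).
    """
    w_lo, w_hi = width_range
    slot = w_hi + 2 * jitter + 200
    slots: list[tuple[str, int]] = []
    for chrom, length in genome.chromosomes:
        slots.extend((chrom, s) for s in range(0, length - slot, slot))
    if n > len(slots):
        raise ValueError(
            f"cannot place {n} non-overlapping sites; genome supports "
            f"{len(slots)} — use a larger genome or fewer sites"
        )
    chosen = rng.choice(len(slots), size=n, replace=False)
    n_promoter = int(round(promoter_bias * n)) if tss_sites else 0
    sites: list[GenomicInterval] = []
    for k, slot_i in enumerate(sorted(chosen)):
        width = int(rng.integers(w_lo, w_hi + 1))
        if k < n_promoter:
            chrom, tss_pos, _strand = tss_sites[rng.integers(len(tss_sites))]
            start = max(0, tss_pos - width // 2)
        else:
            chrom, slot_start = slots[slot_i]
            offset = int(rng.integers(0, slot - width - 2 * jitter))
            start = slot_start + jitter + offset
        sites.append(GenomicInterval(chrom, start, start + width))
    return sorted(sites, key=lambda iv: (iv.chrom, iv.start))


def _detectable_sets(
    n_sites: int, n_reps: int, site_overlap: float, rng: np.random.Generator
) -> list[np.ndarray]:
    """Which sites each replicate can possibly call.

    With full overlap every site is detectable by everyone.  Otherwise a
    ``site_overlap`` fraction is shared and the remainder is split disjointly
    across replicates (each replicate's repertoire = shared + private share).
    """
    if site_overlap >= 1.0:
        return [np.ones(n_sites, dtype=bool) for _ in range(n_reps)]
    perm = rng.permutation(n_sites)
    n_shared = int(round(site_overlap * n_sites))
    shared = perm[:n_shared]
    rest = perm[n_shared:]
    chunks = np.array_split(rest, n_reps)
    sets = []
    for r in range(n_reps):
        mask = np.zeros(n_sites, dtype=bool)
        mask[shared] = True
        mask[chunks[r]] = True
        sets.append(mask)
    return sets


def _jittered_peak(
    iv: GenomicInterval, jitter: int, name: str, rng: np.random.Generator
) -> Peak:
    if jitter > 0:
        ds = int(rng.integers(-jitter, jitter + 1))
        de = int(rng.integers(-jitter, jitter + 1))
    else:
        ds = de = 0
    start = max(0, iv.start + ds)
    end = max(start + 1, iv.end + de)
    new = GenomicInterval(iv.chrom, start, end)
    summit = min(max(iv.midpoint - start, 0), len(new) - 1)
    return Peak(
        interval=new,
        name=name,
        score=int(rng.integers(200, 1001)),
        strand=".",
        signal=float(rng.uniform(1, 20)),
        summit_offset=summit,
    )


def _false_peaks(
    genome: GenomeSpec,
    rate_per_mb: float,
    width_range: tuple[int, int],
    prefix: str,
    rng: np.random.Generator,
) -> list[Peak]:
    peaks = []
    for chrom, length in genome.chromosomes:
        n = rng.poisson(rate_per_mb * length / 1e6)
        for i in range(n):
            width = int(rng.integers(width_range[0], width_range[1] + 1))
            start = int(rng.integers(0, max(1, length - width)))
            iv = GenomicInterval(chrom, start, start + width)
            peaks.append(
                Peak(
                    interval=iv,
                    name=f"{prefix}_fp{chrom}_{i}",
                    score=int(rng.integers(100, 500)),
                    strand=".",
                    signal=float(rng.uniform(0.5, 3)),
                    summit_offset=width // 2,
                )
            )
    return peaks


def _sample_fragments(
    genome: GenomeSpec,
    sites: list[GenomicInterval],
    strengths: np.ndarray,
    rep: ReplicateSpec,
    shift: int,
    experiment_id: str,
    rng: np.random.Generator,
) -> FragmentSet:
    """Multinomial split of the library between background and site mass.

    Background weight is the genome length; each true site adds
    (enrichment_fold - 1) * width * strength extra weight, so the realized
    mean fragment density over sites is enrichment_fold times background,
    modulated per site by its strength multiplier.
    """
    chrom_names = [c for c, _ in genome.chromosomes]
    chrom_lengths = np.array([l for _, l in genome.chromosomes], dtype=float)
    g_total = chrom_lengths.sum()
    site_weights = np.array(
        [
            (rep.enrichment_fold - 1.0) * len(iv) * s
            for iv, s in zip(sites, strengths)
        ],
        dtype=float,
    )
    weights = np.concatenate([[g_total], site_weights])
    probs = weights / weights.sum()
    counts = rng.multinomial(rep.library_size, probs)

    reads: list[tuple[str, int, str]] = []
    # background: chromosome by length, position uniform
    n_bg = counts[0]
    chrom_idx = rng.choice(len(chrom_names), size=n_bg, p=chrom_lengths / g_total)
    positions = (rng.random(n_bg) * chrom_lengths[chrom_idx]).astype(np.int64)
    strands = rng.random(n_bg) < 0.5
    for ci, pos, plus in zip(chrom_idx, positions, strands):
        reads.append((chrom_names[ci], int(pos), "+" if plus else "-"))
    # site mass: centres normal around the site midpoint
    for iv, n_site in zip(sites, counts[1:]):
        if n_site == 0:
            continue
        centers = rng.normal(iv.midpoint, len(iv) / 4, size=n_site)
        centers = np.clip(centers, iv.start, iv.end - 1).astype(np.int64)
        plus = rng.random(n_site) < 0.5
        for c, is_plus in zip(centers, plus):
            reads.append((iv.chrom, int(c), "+" if is_plus else "-"))
    # emit 5' positions such that shifting by `shift` recovers the centre
    shifted_out = [
        (chrom, max(0, pos - shift) if strand == "+" else pos + shift, strand)
        for chrom, pos, strand in reads
    ]
    return FragmentSet.from_reads(experiment_id, shifted_out, shift)


def generate_condition(
    genome: GenomeSpec,
    spec: ConditionSpec,
    tss_sites: Sequence[tuple[str, int, str]] | None = None,
) -> tuple[Condition, dict[str, FragmentSet], GroundTruth]:
    """Simulate one replicated condition from its spec.

    Returns the condition (peak lists per replicate), fragment sets keyed by
    experiment id (empty dict when all library sizes are 0), and the ground
    truth.  Deterministic in ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    sites = _place_sites(
        genome,
        spec.n_true_sites,
        spec.site_width,
        max(r.boundary_jitter for r in spec.replicates),
        rng,
        tss_sites=tss_sites,
        promoter_bias=spec.promoter_bias,
    )
    detectable = _detectable_sets(
        spec.n_true_sites, len(spec.replicates), spec.site_overlap, rng
    )
    # shared latent strength; detection ranks sites on strength + noise
    z = rng.standard_normal(spec.n_true_sites)
    strengths = np.exp(spec.strength_sd * z - spec.strength_sd**2 / 2)
    experiments: list[Experiment] = []
    fragment_sets: dict[str, FragmentSet] = {}
    detected_map: dict[str, np.ndarray] = {}
    detectable_map: dict[str, np.ndarray] = {}
    for r, rep in enumerate(spec.replicates):
        exp_id = f"{spec.condition_id}_rep{r + 1}"
        score = z + spec.detection_noise * rng.standard_normal(spec.n_true_sites)
        candidates = np.flatnonzero(detectable[r])
        k = int(round(rep.detection_sensitivity * len(candidates)))
        top = candidates[np.argsort(score[candidates])[::-1][:k]]
        detected = np.zeros(spec.n_true_sites, dtype=bool)
        detected[top] = True
        peaks = [
            _jittered_peak(sites[i], rep.boundary_jitter, f"{exp_id}_pk{i}", rng)
            for i in np.flatnonzero(detected)
        ]
        peaks += _false_peaks(genome, rep.false_peak_rate, spec.site_width, exp_id, rng)
        experiments.append(
            Experiment(
                id=exp_id,
                condition_id=spec.condition_id,
                peaks=peaks,
            )
        )
        detected_map[exp_id] = detected
        detectable_map[exp_id] = detectable[r]
        if rep.library_size > 0:
            fragment_sets[exp_id] = _sample_fragments(
                genome, sites, strengths, rep, spec.shift, exp_id, rng
            )
    cond = Condition(
        id=spec.condition_id,
        factor="simTF",
        cell_line="simCell",
        treatment="none",
        experiments=experiments,
    )
    truth = GroundTruth(
        condition_id=spec.condition_id,
        true_sites=sites,
        site_strength=strengths,
        detectable=detectable_map,
        detected=detected_map,
        intended_class=spec.intended_class,
    )
    return cond, fragment_sets, truth


def generate_tss(
    genome: GenomeSpec, n_genes: int, seed: int = 0
) -> tuple[TSSIndex, list[TranscriptRecord]]:
    """Random strand-annotated transcripts; returns the TSS index and records."""
    if n_genes <= 0:
        raise ValueError("n_genes must be positive")
    rng = np.random.default_rng(seed)
    chrom_names = [c for c, _ in genome.chromosomes]
    chrom_lengths = np.array([l for _, l in genome.chromosomes], dtype=float)
    records: list[TranscriptRecord] = []
    for i in range(n_genes):
        ci = int(rng.choice(len(chrom_names), p=chrom_lengths / chrom_lengths.sum()))
        length = int(rng.integers(1_000, 10_001))
        max_start = max(1, int(chrom_lengths[ci]) - length)
        start = int(rng.integers(0, max_start))
        strand = "+" if rng.random() < 0.5 else "-"
        records.append(
            TranscriptRecord(
                chrom=chrom_names[ci],
                start=start,
                end=start + length,
                strand=strand,
                transcript_id=f"simT{i:05d}",
            )
        )
    return build_tss_index(records), records


def write_transcripts_gtf(records: Iterable[TranscriptRecord], path: str | Path) -> None:
    """Write transcript records as GTF (1-based closed coordinates)."""
    with open(path, "w") as fh:
        for t in records:
            fh.write(
                f"{t.chrom}\tchipcord_sim\ttranscript\t{t.start + 1}\t{t.end}\t."
                f"\t{t.strand}\t.\ttranscript_id \"{t.transcript_id}\";\n"
            )


def write_fragments_bed(fragments: FragmentSet, path: str | Path, read_length: int = 36) -> None:
    """Write fragments back as BED6 reads whose 5' ends reproduce the set."""
    shift = fragments.shift
    with open(path, "w") as fh:
        for chrom in sorted(fragments.positions):
            for shifted in fragments.positions[chrom]:
                # emit as a + strand read whose 5' end un-shifts correctly
                start = max(0, int(shifted) - shift)
                fh.write(
                    f"{chrom}\t{start}\t{start + read_length}\tread\t0\t+\n"
                )


def generate_dataset(
    specs: Sequence[ConditionSpec],
    out_dir: str | Path,
    genome: GenomeSpec = DEFAULT_GENOME,
    n_genes: int = 0,
    seed: int = 0,
) -> pd.DataFrame:
    """Write a full synthetic dataset (narrowPeak, fragment BED, GTF, manifest).

    Per-condition seeds are derived from ``seed`` so conditions are
    independent; regeneration with the same seed gives identical files.
    Returns the ground-truth table (condition, intended class, site counts).
    """
    ids = [s.condition_id for s in specs]
    if len(set(ids)) != len(ids):
        raise ValueError("condition ids must be unique")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tss_sites = None
    if n_genes > 0:
        idx, records = generate_tss(genome, n_genes, seed=seed + 7)
        write_transcripts_gtf(records, out / "annotation.gtf")
        tss_sites = list(idx.all_sites())

    manifest_rows = []
    truth_rows = []
    for k, spec in enumerate(specs):
        spec = replace(spec, seed=seed + 1000 * (k + 1) + spec.seed)
        cond, fsets, truth = generate_condition(genome, spec, tss_sites=tss_sites)
        for e in cond.experiments:
            # manifest paths are relative to the dataset directory, so
            # regenerated datasets are byte-identical and relocatable
            peak_path = f"{e.id}.narrowPeak"
            write_narrowpeak(e.peaks, out / peak_path)
            frag_path = ""
            if e.id in fsets:
                frag_path = f"{e.id}.fragments.bed"
                write_fragments_bed(fsets[e.id], out / frag_path)
            manifest_rows.append(
                {
                    "experiment_id": e.id,
                    "condition_id": cond.id,
                    "factor": cond.factor,
                    "cell_line": cond.cell_line,
                    "treatment": cond.treatment,
                    "lab": "sim",
                    "antibody": "sim",
                    "peak_path": peak_path,
                    "fragment_path": frag_path,
                }
            )
        truth_rows.append(
            {
                "condition_id": cond.id,
                "intended_class": spec.intended_class or "",
                "n_true_sites": len(truth.true_sites),
                "n_detected": ",".join(
                    str(int(truth.detected[e.id].sum())) for e in cond.experiments
                ),
            }
        )
    manifest_columns = [
        "experiment_id", "condition_id", "factor", "cell_line", "treatment",
        "lab", "antibody", "peak_path", "fragment_path",
    ]
    manifest = pd.DataFrame(manifest_rows, columns=manifest_columns)
    manifest.to_csv(out / "manifest.tsv", sep="\t", index=False)
    truth_df = pd.DataFrame(
        truth_rows,
        columns=["condition_id", "intended_class", "n_true_sites", "n_detected"],
    )
    truth_df.to_csv(out / "ground_truth.tsv", sep="\t", index=False)
    return truth_df


# ---------------------------------------------------------------------------
# frozen margin-separated recovery fixture


def recovery_specs(
    n_per_class: int = 20, base_seed: int = 0, library_size: int = 0
) -> list[ConditionSpec]:
    """Margin-separated condition specs, ``n_per_class`` per concordance class.

    Parameters are chosen so every decision quantity sits well clear (>=0.10)
    of the 0.50 / 2x / 0.70 classification cut-offs:

    * similar: both replicates at sensitivity 0.93, few false peaks —
      expected common fractions ~0.9, size ratio ~1.
    * sensitive: sensitivities 0.95 vs 0.35 on a shared repertoire —
      size ratio ~2.7, small-list fraction ~0.9, large-list fraction ~0.35.
    * dissimilar: 20% shared repertoire at equal sensitivity 0.90 —
      fractions ~0.30, size ratio ~1.
    """
    specs: list[ConditionSpec] = []
    for i in range(n_per_class):
        specs.append(
            ConditionSpec(
                condition_id=f"sim_similar_{i:02d}",
                replicates=(
                    ReplicateSpec(0.93, 1.0, 20, 5.0, library_size),
                    ReplicateSpec(0.93, 1.0, 20, 5.0, library_size),
                ),
                intended_class="similar",
                seed=base_seed + i,
            )
        )
        specs.append(
            ConditionSpec(
                condition_id=f"sim_sensitive_{i:02d}",
                replicates=(
                    ReplicateSpec(0.95, 1.0, 20, 5.0, library_size),
                    ReplicateSpec(0.35, 1.0, 20, 2.5, library_size),
                ),
                intended_class="sensitive",
                seed=base_seed + 100 + i,
            )
        )
        specs.append(
            ConditionSpec(
                condition_id=f"sim_dissimilar_{i:02d}",
                replicates=(
                    ReplicateSpec(0.90, 1.0, 20, 5.0, library_size),
                    ReplicateSpec(0.90, 1.0, 20, 5.0, library_size),
                ),
                site_overlap=0.2,
                intended_class="dissimilar",
                seed=base_seed + 200 + i,
            )
        )
    return specs
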