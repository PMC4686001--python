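# Methods

## Coordinate and overlap model

All intervals are 0-based half-open; `|[a,b)| = b − a`. Two intervals
overlap iff they are on the same chromosome and `max(starts) < min(ends)` —
i.e. they share at least one base. Abutting half-open intervals
(`[a,b)` next to `[b,c)`) do **not** overlap and are never merged.
Chromosome names are compared by literal string equality. Strand is ignored
in every overlap computation (ChIP peaks are unstranded). Peaks within one
list are kept exactly as read — no deduplication or pre-merging — so peak
counts match the caller's output row for row.

Two senses of "common" coexist deliberately:

* `common_regions` — maximal genomic segments covered by ≥1 peak of every
  replicate (iterated pairwise intersection of each list's merged
  coverage). These drive the per-experiment overlap *fractions*.
* the `common` member of a `PeakPartition` — an experiment's *native* peaks
  that overlap every other replicate. These preserve native widths and are
  what coverage and FPKM statistics are computed on.

Overlap fractions are computed over peak counts, not base pairs.

## Classification

With per-experiment fractions f_e of peaks overlapping the common regions:
*similar* iff f_e ≥ 0.50 for all e; else *sensitive* iff
max n_peaks ≥ 2.0 × min n_peaks **and** the smallest list's fraction
> 0.70; else *dissimilar*. Boundary semantics (inclusive 0.50 and 2×,
strict 0.70) follow the rule's wording; all three cut-offs are fields of
`ClassThresholds`. For more than two replicates the sensitivity rule
compares the largest against the smallest list and tests the smallest
list's fraction — the most conservative single reading of the pairwise
rule; this is a configurable choice, not the only defensible one.

Recommendations: union of replicate peaks for similar/sensitive;
for dissimilar, a caller-named replicate (clustering/TSS/motif evidence is
supplied externally) or, failing that, the intersection with a warning.

## Fragment model and enrichment metrics

A read is reduced to one point: its 5′ position shifted +s on the + strand
and −s on the − strand, s = 150 bp by default (a typical fragment
half-length). No read extension is applied; the same single shift is used
by coverage profiles and MA counting so the two stages see identical
counts. Library size is the number of fragments supplied (assumed already
deduplicated and uniquely aligned); FPKM and FRiP are therefore invariant
to duplicating every fragment.

Coverage profiles use windows of ±2000 bp around peak **midpoints** with
10 bp bins. The window extent and bin size are package choices (configurable);
midpoint anchoring is used uniformly because undetected regions have no
native summit. Empty peak sets give NaN curves, distinguishing "no peaks"
from "no signal". Windows extending below coordinate 0 are counted as-is
(no fragments exist there) and tallied in a `clipped` counter.

## TSS distances

TSS = transcript start for + strand, `end − 1` for − strand; transcripts
sharing a TSS collapse to one indexed position. Distance is measured from
the peak midpoint to the nearest TSS by absolute value and signed by gene
orientation: positive when the midpoint lies 3′ (downstream) of the TSS.
Ties on absolute distance — including a single position carrying both
strands — resolve to the downstream (positive) alternative. This sign
convention is a package definition, chosen so "a higher proportion of
peaks downstream of a TSS" is a computable criterion. "Overlapping a TSS"
means the TSS coordinate lies within `[start, end)` of the peak. GTF input
(1-based closed) is converted on read.

## MA normalization and differential test

Regions are the merged union of both replicates' peaks; a region is
*common* when it overlaps at least one peak of each list. With pseudocount
c = 0.5:

    M = log2((x1+c)/(x2+c)),  A = ½·log2((x1+c)(x2+c))

The normalization line M = a + b·A is fitted on common regions only, by
iteratively reweighted least squares with Huber weights (k = 1.345, ≤50
iterations, 10⁻⁸ coefficient tolerance; statsmodels RLM). Robustness
matters because genuinely differential common regions act as outliers;
Huber's k = 1.345 keeps ~95 % normal-theory efficiency. At least 10 common
regions are required — fewer means the condition is too discordant to
normalize, and the fit refuses explicitly.

Normalized counts are reconstructed as x1′ = 2^(A + M_norm/2),
x2′ = 2^(A − M_norm/2) (preserving the product (x1+c)(x2+c)), rounded to
non-negative integers, and each region is tested with a two-sided exact
binomial test of x1′ successes in x1′+x2′ trials at p = ½ (vectorized via
the symmetry identity p = min(1, 2·min(cdf, sf)); equality with
`scipy.stats.binomtest` is asserted in the tests). Significance is raw
p < 0.01 by default — the fractions reported are of nominally significant
regions — with Benjamini–Hochberg correction behind a flag. The pseudocount
and alpha are package defaults, configurable. Reported bands: fraction
> 0.50 "majority-differential", < 0.25 "concordant".

## Occupancy clustering

The region universe is the merged union of all experiments' peaks; entry
(r, e) is 1 iff experiment e has a peak overlapping region r. Pearson
correlation between binary columns equals the phi coefficient of the 2×2
co-occupancy table. Clustering is agglomerative on d = 1 − r with complete
linkage by default (average/single selectable); experiments are sorted
lexicographically before clustering so equal-distance merges are
deterministic. Constant columns yield NaN correlations with a warning;
strict mode refuses to cluster them, lenient mode substitutes the worst
observed distance. Dendrograms export as Newick with branch lengths.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes,
with every random draw flowing from one integer seed
(`numpy.random.default_rng`); identical seeds give byte-identical files.

* **Genome**: two chromosomes, 1.5 Mb + 1.0 Mb by default — large enough
  that false-peak/true-site collisions are rare at the default densities,
  small enough that a full 60-condition dataset generates in ~1 s.
* **Sites**: n_true_sites (default 300) placed without overlap via slot
  sampling; widths uniform in 200–400 bp. Each site carries a strength
  multiplier exp(τ·z − τ²/2), z ~ N(0,1), τ = 0.5 (mean 1), emulating the
  wide dynamic range of real binding sites.
* **Detection**: each replicate ranks its detectable sites by z plus
  independent N(0,1) noise and calls the top `detection_sensitivity`
  fraction. Detection is thus *signal-coupled*: sites a replicate misses
  are weaker on average, which is what makes observed coverage at
  "undetected" peaks intermediate — clearly above background but below
  common peaks — rather than either zero or indistinguishable from common.
  An independent-Bernoulli detection model cannot produce that ordering.
* **Class mechanisms**: *similar* = matched high sensitivities; *sensitive*
  = one replicate with much lower sensitivity (efficiency difference);
  *dissimilar* = partially disjoint detectable repertoires
  (`site_overlap`: the shared fraction; the remainder split disjointly),
  emulating e.g. antibodies with different isoform specificity.
* **Peaks**: detected sites with edges jittered ±20 bp, plus false peaks
  as a Poisson process (default 1–2 per Mb).
* **Fragments**: the library (multinomial, exact `library_size`) splits
  between a uniform background (weight = genome length) and per-site extra
  mass (weight = (enrichment_fold − 1) · width · strength), so mean site
  density is enrichment_fold × background. Enrichment attaches to *true
  sites*, not to called peaks. Fragment centres are normal around the site
  midpoint (sd = width/4); each fragment is emitted as a strand-random 5′
  read position offset by the read shift, so un-shifting recovers centres.
* **TSS**: random strand-annotated transcripts (1–10 kb); a
  `promoter_bias` fraction of true sites can be re-centred on sampled TSS
  positions.

What the generator does **not** emulate: sequence content and mappability,
duplicate reads, input/control structure, copy-number variation,
chromatin-state-dependent background, and realistic peak-caller behaviour
(detection is an abstract ranking, not SPP). Tests passing on this
generator therefore validate the *analysis logic* — the overlap algebra,
classification rules, normalization and metrics — under the stated
statistical assumptions, not robustness to every artefact of real ChIP-seq.

### Recovery fixture

`recovery_specs()` freezes a margin-separated 60-condition design
(20 per class) in code: similar = sensitivities (0.93, 0.93); sensitive =
(0.95, 0.35), giving size ratio ≈ 2.7 and small-list fraction ≈ 0.95;
dissimilar = site_overlap 0.2 at sensitivity 0.90, giving fractions ≈ 0.30
at size ratio ≈ 1. Every decision quantity sits ≥ 0.10 from its
classification cut-off (asserted as a test), so correct recovery is the
expected outcome and failures indicate implementation defects, not
borderline draws.

### Simulation scales

Validation simulations use 150–300 sites on the 2.5 Mb genome with
libraries of 3–5×10⁴ fragments (site-level counts then match typical
deeply-sequenced ChIP peaks); MA calibration uses 1000–2000 regions with
Poisson rates drawn log-uniform on [30, 1000] — peak intensities span
orders of magnitude, and a wide rate spread is also what identifies the
normalization line's slope separately from its intercept (for unequal
Poisson rates Cov(M, A) is genuinely nonzero, so a narrow A range lets
slope error leak into the extrapolated intercept).

## Numerical and degenerate-input choices

* Empty peak lists are a validation error naming the experiment; a
  single-experiment condition cannot be partitioned or classified.
* narrowPeak columns 7–10 are optional; missing values read as None
  (summit −1) and write back as −1 per convention. Negative p/q
  sentinels in files are treated as missing.
* x1′+x2′ = 0 regions get p = 1.
* Dendrogram heights live in [0, 2] because d = 1 − r does.
* Manifest paths may be relative; they resolve against the manifest's own
  directory, making generated datasets relocatable and regeneration
  byte-identical.

## Known limitations

* The sensitive rule for >2 replicates (largest vs smallest) is one
  reading of a rule stated for pairs; pairwise application can classify
  differently on ≥3-replicate conditions.
* MA analysis is defined for replicate pairs; conditions with more
  replicates must be analysed pairwise by the caller.
* The exact binomial test ignores overdispersion between biological
  replicates; its raw-p fractions are descriptive, not inferential.
* TSS annotation assumes the annotation matches the peak assembly; no
  coordinate lift-over is provided.
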