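"""Fragment counting, FPKM/FRiP and coverage profiles vs closed forms and scans."""

import numpy as np
import pytest

from chipcord.coverage import (
    FragmentSet,
    count_fragments,
    coverage_profile,
    depth_vs_peaks,
    frip,
    peak_fpkm,
    read_fragments_bed,
)
from chipcord.intervals import (
    Condition,
    Experiment,
    GenomicInterval,
    PeakPartition,
    partition_condition,
)
from chipcord.simulate import ConditionSpec, DEFAULT_GENOME, ReplicateSpec, generate_condition

from conftest import make_peaks


def _fragset(positions, shift=0, chrom="chr1"):
    return FragmentSet("e", {chrom: np.array(positions)}, shift)


class TestCountFragments:
    def test_half_open_counting(self):
        fs = FragmentSet.from_reads("e", [("chr1", 100, "+"), ("chr1", 150, "+"), ("chr1", 199, "+")], shift=0)
        assert count_fragments(GenomicInterval("chr1", 100, 200), fs) == 3
        assert count_fragments(GenomicInterval("chr1", 100, 199), fs) == 2

    def test_shift_moves_plus_reads_downstream(self):
        fs = FragmentSet.from_reads("e", [("chr1", 100, "+")], shift=150)
        assert count_fragments(GenomicInterval("chr1", 100, 200), fs) == 0
        assert count_fragments(GenomicInterval("chr1", 200, 300), fs) == 1

    def test_shift_moves_minus_reads_upstream(self):
        fs = FragmentSet.from_reads("e", [("chr1", 400, "-")], shift=150)
        assert count_fragments(GenomicInterval("chr1", 200, 300), fs) == 1

    def test_binary_search_equals_linear_scan(self, rng):
        pos = rng.integers(0, 100_000, size=10_000)
        fs = _fragset(pos)
        for _ in range(100):
            start = int(rng.integers(0, 99_000))
            end = start + int(rng.integers(1, 2_000))
            region = GenomicInterval("chr1", start, end)
            linear = int(np.sum((pos >= start) & (pos < end)))
            assert count_fragments(region, fs) == linear

    def test_additive_over_bin_partition(self, rng):
        fs = _fragset(rng.integers(0, 10_000, size=2_000))
        whole = GenomicInterval("chr1", 1_000, 2_000)
        parts = [GenomicInterval("chr1", s, s + 100) for s in range(1_000, 2_000, 100)]
        assert count_fragments(whole, fs) == sum(count_fragments(p, fs) for p in parts)


class TestFPKM:
    def test_formula(self):
        fs = _fragset(np.arange(100, 120))  # 20 fragments in the peak
        # pad library to 10^7 with far-away fragments
        fs = FragmentSet(
            "e", {"chr1": np.concatenate([np.arange(100, 120), np.full(10_000_000 - 20, 10_000)])}, 0
        )
        assert peak_fpkm(GenomicInterval("chr1", 0, 500), fs) == pytest.approx(4.0)

    def test_zero_fragments(self):
        fs = _fragset([5_000])
        assert peak_fpkm(GenomicInterval("chr1", 0, 500), fs) == 0.0

    def test_empty_library_rejected(self):
        fs = FragmentSet("e", {})
        with pytest.raises(ValueError):
            peak_fpkm(GenomicInterval("chr1", 0, 500), fs)

    def test_uniform_poisson_matches_closed_form(self, rng):
        # uniform fragments on [0, L): expected FPKM = 1e9 / L independent of rate
        L = 1_000_000
        n = 200_000
        fs = _fragset(rng.integers(0, L, size=n))
        peaks = []
        for _ in range(200):
            s = int(rng.integers(0, L - 1_000))
            peaks.append(GenomicInterval("chr1", s, s + 1_000))
        vals = [peak_fpkm(p, fs) for p in peaks]
        expected = 1e9 / L
        se = expected / np.sqrt(n * 1_000 / L) / np.sqrt(len(peaks))
        assert abs(np.mean(vals) - expected) < 3 * se

    def test_invariant_to_fragment_duplication(self, rng):
        pos = rng.integers(0, 10_000, size=1_000)
        region = GenomicInterval("chr1", 2_000, 3_000)
        single = _fragset(pos)
        doubled = _fragset(np.concatenate([pos, pos]))
        assert peak_fpkm(region, single) == pytest.approx(peak_fpkm(region, doubled))


class TestFRiP:
    def test_all_fragments_inside(self):
        fs = _fragset([10, 20, 30])
        assert frip(make_peaks([("chr1", 0, 100)]), fs) == 1.0

    def test_simple_fraction(self, rng):
        inside = rng.integers(0, 100, size=50)
        outside = rng.integers(10_000, 20_000, size=950)
        fs = _fragset(np.concatenate([inside, outside]))
        assert frip(make_peaks([("chr1", 0, 100)]), fs) == pytest.approx(0.05)

    def test_overlapping_peaks_count_no_fragment_twice(self, rng):
        pos = rng.integers(0, 5_000, size=3_000)
        fs = _fragset(pos)
        peaks = make_peaks([("chr1", 0, 1_000), ("chr1", 500, 1_500), ("chr1", 900, 1_100)])
        # per-fragment membership oracle
        expected = np.mean([(p >= 0) & (p < 1_500) for p in pos])
        assert frip(peaks, fs) == pytest.approx(float(expected))


class TestCoverageProfile:
    def _partition(self, common, specific=(), undetected=()):
        return PeakPartition(
            "e",
            common=make_peaks(common),
            sample_specific=make_peaks(specific),
            undetected=[GenomicInterval(*t) for t in undetected],
        )

    def test_central_bin_carries_point_mass(self):
        part = self._partition([("chr1", 9_000, 11_000)])  # midpoint 10_000
        fs = _fragset([10_000] * 50)
        prof = coverage_profile(part, fs, window_half_width=500, bin_width=10)
        curve = prof.curves["common"]
        center_bin = 500 // 10  # first bin right of the midpoint
        assert curve[center_bin] > 0
        assert np.sum(curve > 0) == 1

    def test_empty_set_is_nan_not_zero(self):
        part = self._partition([("chr1", 0, 200)])
        prof = coverage_profile(part, _fragset([100]), 500, 10)
        assert np.isnan(prof.curves["sample_specific"]).all()
        assert np.isnan(prof.curves["undetected"]).all()

    def test_uniform_background_is_flat_within_3se(self, rng):
        L, n = 500_000, 300_000
        fs = _fragset(rng.integers(0, L, size=n))
        centers = rng.integers(50_000, L - 50_000, size=100)
        part = self._partition([("chr1", int(c) - 100, int(c) + 100) for c in centers])
        prof = coverage_profile(part, fs, window_half_width=1_000, bin_width=50)
        curve = prof.curves["common"]
        rate_per_bin = n * 50 / L  # expected fragments per bin per peak
        expected_fpkm = rate_per_bin / ((50 / 1e3) * (n / 1e6))
        se_fpkm = expected_fpkm / np.sqrt(rate_per_bin * 100)
        assert np.all(np.abs(curve - expected_fpkm) < 3 * se_fpkm * np.sqrt(100) / 3)
        # mean over bins is much tighter
        assert abs(curve.mean() - expected_fpkm) < 3 * se_fpkm

    def test_profile_mass_equals_window_counts(self, rng):
        fs = _fragset(rng.integers(0, 20_000, size=5_000))
        part = self._partition([("chr1", 9_000, 11_000)])
        prof = coverage_profile(part, fs, 1_000, 10)
        lib_millions = fs.library_size / 1e6
        mass = np.sum(prof.curves["common"] * (10 / 1e3) * lib_millions)
        window_count = count_fragments(GenomicInterval("chr1", 9_000, 11_000), fs)
        assert mass == pytest.approx(window_count)

    def test_bin_width_must_divide_window(self):
        with pytest.raises(ValueError):
            coverage_profile(self._partition([("chr1", 0, 100)]), _fragset([1]), 500, 7)

    def test_enriched_condition_orders_common_above_undetected(self):
        spec = ConditionSpec(
            "cov",
            (
                ReplicateSpec(0.8, 2.0, 20, 5.0, 50_000),
                ReplicateSpec(0.8, 2.0, 20, 5.0, 50_000),
            ),
            n_true_sites=200,
            seed=11,
        )
        cond, fsets, _ = generate_condition(DEFAULT_GENOME, spec)
        for part in partition_condition(cond):
            prof = coverage_profile(part, fsets[part.experiment_id], 2_000, 10)
            means = {k: np.nanmean(v) for k, v in prof.curves.items()}
            assert means["common"] > means["undetected"]


class TestDepthVsPeaks:
    def _cond_with_sizes(self, n1, n2):
        return Condition(
            id="c",
            experiments=[
                Experiment(id="e1", peaks=make_peaks([("chr1", i * 1000, i * 1000 + 100) for i in range(n1)])),
                Experiment(id="e2", peaks=make_peaks([("chr1", i * 1000, i * 1000 + 100) for i in range(n2)])),
            ],
        )

    def test_depth_concordant_when_more_reads_more_peaks(self, rng):
        cond = self._cond_with_sizes(40, 10)
        fsets = {
            "e1": _fragset(rng.integers(0, 50_000, size=30_000)),
            "e2": _fragset(rng.integers(0, 50_000, size=10_000)),
        }
        rec = depth_vs_peaks(cond, fsets)
        assert rec["depth_concordant"] is True

    def test_depth_discordant_case(self, rng):
        cond = self._cond_with_sizes(40, 10)
        fsets = {
            "e1": _fragset(rng.integers(0, 50_000, size=10_000)),
            "e2": _fragset(rng.integers(0, 50_000, size=30_000)),
        }
        assert depth_vs_peaks(cond, fsets)["depth_concordant"] is False

    def test_missing_fragments_gives_partial_record(self, rng):
        cond = self._cond_with_sizes(5, 5)
        rec = depth_vs_peaks(cond, {"e1": _fragset(rng.integers(0, 1_000, 100))})
        assert rec["missing_fragments"] == ["e2"]
        assert "depth_concordant" not in rec

    def test_enrichment_concordance_under_efficiency_differences(self):
        """Replicates differing in ChIP efficiency (enrichment + sensitivity
        jointly lowered) have peak counts tracking enrichment, not depth."""
        hits = 0
        n_runs = 25
        for seed in range(n_runs):
            spec = ConditionSpec(
                "eff",
                (
                    ReplicateSpec(0.9, 1.0, 20, 6.0, 30_000),
                    ReplicateSpec(0.45, 1.0, 20, 2.5, 30_000),
                ),
                n_true_sites=150,
                seed=seed,
            )
            cond, fsets, _ = generate_condition(DEFAULT_GENOME, spec)
            rec = depth_vs_peaks(cond, fsets)
            hits += rec["enrichment_concordant"]
        assert hits >= 0.95 * n_runs


class TestBedReader:
    def test_five_prime_inference(self, tmp_path):
        bed = tmp_path / "reads.bed"
        bed.write_text("chr1\t100\t136\tr1\t0\t+\nchr1\t200\t236\tr2\t0\t-\n")
        fs = read_fragments_bed(bed, "e", shift=0)
        assert list(fs.positions["chr1"]) == [100, 235]
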