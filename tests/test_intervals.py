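"""Interval model, narrowPeak I/O, and overlap operators vs brute-force oracles."""

import numpy as np
import pytest

from chipcord.intervals import (
    Condition,
    Experiment,
    GenomicInterval,
    NarrowPeakParseError,
    Peak,
    _parse_line,
    common_regions,
    merge_intervals,
    merge_regions,
    overlap_length,
    overlaps,
    partition_condition,
    read_narrowpeak,
    total_bp,
    write_narrowpeak,
)

from conftest import (
    bases_to_intervals,
    brute_overlaps,
    covered_bases,
    make_peaks,
    random_intervals,
    random_peaks,
)


class TestTypes:
    def test_interval_validation(self):
        with pytest.raises(ValueError):
            GenomicInterval("chr1", -1, 10)
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 10, 10)
        with pytest.raises(ValueError):
            GenomicInterval("", 0, 10)

    def test_half_open_length(self):
        assert len(GenomicInterval("chr1", 100, 250)) == 150

    def test_summit_must_fit_inside_peak(self):
        with pytest.raises(ValueError):
            Peak(interval=GenomicInterval("chr1", 0, 100), summit_offset=100)

    def test_duplicate_experiment_ids_rejected(self):
        e = Experiment(id="a")
        with pytest.raises(ValueError):
            Condition(id="c", experiments=[e, Experiment(id="a")])

    def test_experiment_sorts_peaks(self):
        peaks = make_peaks([("chr2", 5, 10), ("chr1", 50, 60), ("chr1", 5, 10)])
        e = Experiment(id="x", peaks=peaks)
        keys = [(p.chrom, p.start) for p in e.peaks]
        assert keys == sorted(keys)


class TestNarrowPeakIO:
    def test_full_ten_column_line(self):
        p = _parse_line("chr1\t100\t600\tpk1\t800\t.\t5.2\t10.1\t8.3\t250", 1)
        assert (p.chrom, p.start, p.end) == ("chr1", 100, 600)
        assert p.name == "pk1" and p.score == 800
        assert p.signal == 5.2 and p.neg_log10_p == 10.1 and p.neg_log10_q == 8.3
        assert p.summit_offset == 250

    def test_bed6_line_has_missing_optionals(self):
        p = _parse_line("chr1\t100\t600\tpk1\t800\t.", 1)
        assert p.signal is None and p.neg_log10_p is None and p.neg_log10_q is None
        assert p.summit_offset == -1

    def test_malformed_line_names_line_number(self, tmp_path):
        path = tmp_path / "bad.narrowPeak"
        path.write_text("chr1\t100\t600\tp\t0\t.\n" "chr1\tnope\t700\tp\t0\t.\n")
        with pytest.raises(NarrowPeakParseError, match="line 2"):
            read_narrowpeak(path)

    def test_end_not_after_start_rejected(self, tmp_path):
        path = tmp_path / "bad.narrowPeak"
        path.write_text("chr1\t600\t600\tp\t0\t.\n")
        with pytest.raises(NarrowPeakParseError, match="exceed"):
            read_narrowpeak(path)

    def test_round_trip_preserves_records_and_bytes(self, tmp_path, rng):
        peaks = []
        for i, iv in enumerate(random_intervals(rng, 50)):
            peaks.append(
                Peak(
                    interval=iv,
                    name=f"pk{i}",
                    score=int(rng.integers(0, 1001)),
                    strand=".",
                    signal=float(np.round(rng.uniform(0, 30), 3)),
                    neg_log10_p=float(np.round(rng.uniform(0, 50), 3)),
                    neg_log10_q=float(np.round(rng.uniform(0, 50), 3)),
                    summit_offset=len(iv) // 2,
                )
            )
        p1 = tmp_path / "a.narrowPeak"
        p2 = tmp_path / "b.narrowPeak"
        write_narrowpeak(peaks, p1)
        again = read_narrowpeak(p1)
        write_narrowpeak(again, p2)
        assert p1.read_bytes() == p2.read_bytes()
        assert again == sorted(peaks, key=lambda p: (p.chrom, p.start, p.end))

    def test_gzip_transparent(self, tmp_path, rng):
        peaks = random_peaks(rng, 10)
        path = tmp_path / "a.narrowPeak.gz"
        write_narrowpeak(peaks, path)
        assert len(read_narrowpeak(path)) == 10


class TestOverlaps:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            (("chr1", 100, 200), ("chr1", 199, 300), True),  # 1 bp shared
            (("chr1", 100, 200), ("chr1", 200, 300), False),  # half-open abutment
            (("chr1", 100, 200), ("chr2", 100, 200), False),  # chrom mismatch
            (("chr1", 100, 200), ("chr1", 0, 500), True),  # containment
        ],
    )
    def test_boundary_cases(self, a, b, expected):
        assert overlaps(GenomicInterval(*a), GenomicInterval(*b)) is expected

    def test_agrees_with_per_base_oracle(self, rng):
        xs = random_intervals(rng, 30, max_start=800, max_len=100)
        ys = random_intervals(rng, 30, max_start=800, max_len=100)
        for a in xs:
            for b in ys:
                assert overlaps(a, b) == brute_overlaps(a, b)
                assert overlap_length(a, b) == len(
                    covered_bases([a]) & covered_bases([b])
                )


class TestMergeAndCommon:
    def test_merge_overlapping(self):
        merged = merge_regions(make_peaks([("chr1", 100, 200)]), make_peaks([("chr1", 150, 250)]))
        assert merged == [GenomicInterval("chr1", 100, 250)]

    def test_merge_keeps_abutting_separate(self):
        merged = merge_regions(make_peaks([("chr1", 100, 200), ("chr1", 200, 300)]))
        assert len(merged) == 2

    def test_merge_matches_per_base_oracle(self, rng):
        # abutting-but-not-overlapping intervals stay separate, so compare
        # covered bases and total bp, not interval boundaries
        for _ in range(20):
            ivs = random_intervals(rng, 40)
            merged = merge_intervals(ivs)
            assert covered_bases(merged) == covered_bases(ivs)
            assert total_bp(merged) == len(covered_bases(ivs))
            for a, b in zip(merged, merged[1:]):
                assert not (a.chrom == b.chrom and b.start < a.end)

    def test_common_simple_intersection(self):
        out = common_regions(
            make_peaks([("chr1", 100, 300)]), make_peaks([("chr1", 200, 400)])
        )
        assert out == [GenomicInterval("chr1", 200, 300)]

    def test_common_disjoint_is_empty(self):
        assert (
            common_regions(
                make_peaks([("chr1", 0, 100)]), make_peaks([("chr1", 500, 600)])
            )
            == []
        )

    def test_common_needs_two_lists(self):
        with pytest.raises(ValueError):
            common_regions(make_peaks([("chr1", 0, 100)]))

    def test_common_matches_per_base_oracle_three_lists(self, rng):
        for _ in range(10):
            lists = [random_peaks(rng, 40) for _ in range(3)]
            expected_bases = (
                covered_bases(p.interval for p in lists[0])
                & covered_bases(p.interval for p in lists[1])
                & covered_bases(p.interval for p in lists[2])
            )
            got = common_regions(*lists)
            assert covered_bases(got) == expected_bases

    def test_bp_bounds_invariants(self, rng):
        lists = [random_peaks(rng, 30) for _ in range(3)]
        per_list = [total_bp(merge_regions(pl)) for pl in lists]
        assert total_bp(common_regions(*lists)) <= min(per_list)
        assert total_bp(merge_regions(*lists)) >= max(per_list)


class TestPartition:
    def _cond(self, *peak_lists):
        return Condition(
            id="c",
            experiments=[
                Experiment(id=f"e{i}", peaks=pl) for i, pl in enumerate(peak_lists)
            ],
        )

    def test_forced_two_replicate_example(self):
        cond = self._cond(
            make_peaks([("chr1", 0, 100), ("chr1", 200, 300)]),
            make_peaks([("chr1", 250, 350)]),
        )
        parts = {p.experiment_id: p for p in partition_condition(cond)}
        p0, p1 = parts["e0"], parts["e1"]
        assert [p.interval for p in p0.common] == [GenomicInterval("chr1", 200, 300)]
        assert [p.interval for p in p0.sample_specific] == [
            GenomicInterval("chr1", 0, 100)
        ]
        assert p0.undetected == []
        assert [p.interval for p in p1.common] == [GenomicInterval("chr1", 250, 350)]
        assert p1.sample_specific == []
        assert p1.undetected == [GenomicInterval("chr1", 0, 100)]

    def test_identical_replicates_have_nothing_specific(self, rng):
        peaks = random_peaks(rng, 30)
        cond = self._cond(peaks, list(peaks))
        for part in partition_condition(cond):
            assert part.sample_specific == [] and part.undetected == []

    def test_single_experiment_rejected(self, rng):
        with pytest.raises(ValueError):
            partition_condition(self._cond(random_peaks(rng, 5)))

    def test_matches_nested_loop_oracle_three_replicates(self, rng):
        lists = [random_peaks(rng, 40) for _ in range(3)]
        cond = self._cond(*lists)
        parts = {p.experiment_id: p for p in partition_condition(cond)}
        for i, own in enumerate(lists):
            others = [l for j, l in enumerate(lists) if j != i]
            part = parts[f"e{i}"]
            for p in own:
                hits = [
                    any(overlaps(p.interval, q.interval) for q in ol) for ol in others
                ]
                if all(hits):
                    assert p in part.common
                elif not any(hits):
                    assert p in part.sample_specific
                else:
                    assert p not in part.common and p not in part.sample_specific
            # undetected: merged other coverage with no own overlap
            for iv in part.undetected:
                assert not any(overlaps(iv, q.interval) for q in own)

    def test_symmetric_under_relabeling(self, rng):
        lists = [random_peaks(rng, 25) for _ in range(3)]
        cond_a = self._cond(*lists)
        cond_b = self._cond(*reversed(lists))
        parts_a = {p.experiment_id: p for p in partition_condition(cond_a)}
        parts_b = {p.experiment_id: p for p in partition_condition(cond_b)}
        # e0 in A corresponds to e2 in B
        assert parts_a["e0"].common == parts_b["e2"].common
        assert parts_a["e0"].sample_specific == parts_b["e2"].sample_specific
        assert parts_a["e0"].undetected == parts_b["e2"].undetected

    def test_two_replicate_count_conservation(self, rng):
        lists = [random_peaks(rng, 30) for _ in range(2)]
        cond = self._cond(*lists)
        for i, part in enumerate(partition_condition(cond)):
            assert len(part.common) + len(part.sample_specific) == len(lists[i])
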