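"""Completeness, evenness, GC and panel statistics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from capdepth import (
    CoverageProfile,
    GenomicInterval,
    IntervalSet,
    PanelDefinition,
    TranscriptModel,
    completeness,
    evenness,
    gc_fraction,
    gc_stratification,
    load_depth,
    low_coverage_regions,
    panel_coverage,
    subtract,
    total_bp,
)


def profile(depths, *, start=0, chrom="c"):
    t = IntervalSet([GenomicInterval(chrom, start, start + len(depths))], merged=True)
    return CoverageProfile(t, np.asarray(depths, dtype=np.int64))


class TestLoadDepth:
    def test_constant_bedgraph(self):
        t = IntervalSet([GenomicInterval("chr1", 0, 10)])
        p = load_depth("chr1\t0\t10\t5\n", t, is_text=True)
        assert p.mean_coverage == 5 and list(p.depth) == [5] * 10

    def test_empty_track_gives_zeros(self):
        t = IntervalSet([GenomicInterval("chr1", 0, 10)])
        p = load_depth("", t, is_text=True)
        assert p.mean_coverage == 0

    def test_two_record_expansion_over_partial_target(self):
        t = IntervalSet([GenomicInterval("c", 2, 8)])
        p = load_depth("c\t0\t5\t3\nc\t5\t10\t7\n", t, is_text=True)
        assert list(p.depth) == [3, 3, 3, 7, 7, 7] and p.mean_coverage == 5

    def test_overlapping_records_rejected(self):
        t = IntervalSet([GenomicInterval("c", 0, 10)])
        with pytest.raises(ValueError, match="overlapping"):
            load_depth("c\t0\t6\t3\nc\t4\t10\t7\n", t, is_text=True)

    def test_per_base_tsv_dialect(self):
        t = IntervalSet([GenomicInterval("c", 0, 3)])
        p = load_depth("c\t0\t4\nc\t1\t5\nc\t2\t6\n", t, is_text=True)
        assert list(p.depth) == [4, 5, 6]


class TestCompleteness:
    def test_all_above(self):
        assert completeness(profile([25] * 8), 20).fraction_covered == 1.0

    def test_half_above(self):
        assert completeness(profile([10, 10, 30, 30]), 20).fraction_covered == 0.5

    def test_against_count_oracle(self, rng):
        d = rng.integers(0, 60, 1000)
        got = completeness(profile(d), 20).fraction_covered
        assert got == np.sum(d >= 20) / 1000

    def test_monotone_in_threshold(self, rng):
        d = rng.integers(0, 80, 500)
        fr = [completeness(profile(d), t).fraction_covered for t in range(1, 60, 5)]
        assert all(b <= a for a, b in zip(fr, fr[1:]))

    def test_fraction_is_base_weighted_mean_of_per_target(self, rng):
        t = IntervalSet(
            [GenomicInterval("c", 0, 30), GenomicInterval("c", 100, 170)], merged=True
        )
        p = CoverageProfile(t, rng.integers(0, 50, 100))
        res = completeness(p, 20)
        weighted = (res.per_target_fractions[0] * 30 + res.per_target_fractions[1] * 70) / 100
        assert res.fraction_covered == pytest.approx(weighted, abs=1e-12)


class TestEvenness:
    def test_uniform_is_one(self):
        assert evenness(np.array([7, 7, 7, 7])) == 1.0

    @pytest.mark.parametrize("method", ["closed_form", "cumulative"])
    def test_half_redistribution(self, method):
        assert evenness(np.array([0, 2]), method) == pytest.approx(0.5)

    @pytest.mark.parametrize("method", ["closed_form", "cumulative"])
    def test_two_thirds(self, method):
        assert evenness(np.array([1, 1, 4]), method) == pytest.approx(2 / 3)

    def test_all_zero_undefined(self):
        with pytest.raises(ValueError):
            evenness(np.zeros(5, dtype=int))

    @given(st.lists(st.integers(0, 200), min_size=2, max_size=50).filter(lambda d: sum(d) > 0),
           st.integers(2, 7))
    @settings(max_examples=100, deadline=None)
    def test_scale_invariance_exact(self, depths, m):
        d = np.asarray(depths)
        assert evenness(d) == evenness(d * m)

    @given(st.lists(st.integers(0, 50), min_size=2, max_size=40))
    @settings(max_examples=100, deadline=None)
    def test_oracle_equivalence_integer_mean(self, depths):
        d = np.asarray(depths)
        n = len(d)
        d[-1] += (-int(d.sum())) % n  # force an integer mean
        if d.sum() == 0:
            d += 1
        assert evenness(d) == pytest.approx(evenness(d, "cumulative"), abs=1e-9)

    def test_at_most_one_and_one_only_if_constant(self, rng):
        d = rng.integers(0, 40, 200)
        d[0] += 1  # guarantee non-constant, non-zero
        assert evenness(d) < 1.0


class TestLowCoverageRegions:
    def test_none_when_all_covered(self):
        assert len(low_coverage_regions(profile([30] * 10), 20)) == 0

    def test_run_extraction(self):
        d = [30] * 3 + [5, 5, 5] + [30] * 4
        got = low_coverage_regions(profile(d), 20)
        assert [(iv.start, iv.end) for iv in got] == [(3, 6)]

    def test_runs_do_not_cross_target_boundaries(self):
        t = IntervalSet(
            [GenomicInterval("c", 0, 5), GenomicInterval("c", 10, 15)], merged=True
        )
        p = CoverageProfile(t, np.zeros(10, dtype=np.int64))
        assert len(low_coverage_regions(p, 20)) == 2

    def test_tiles_targets_with_complement(self, rng):
        p = profile(rng.integers(0, 40, 300))
        low = low_coverage_regions(p, 20)
        assert total_bp(low) + total_bp(subtract(p.targets, low)) == 300


class TestGC:
    @pytest.mark.parametrize("seq,expected", [("ATGC", 0.5), ("GGGG", 1.0), ("ANGC", 2 / 3)])
    def test_gc_fraction(self, seq, expected):
        assert gc_fraction(seq) == pytest.approx(expected)

    def test_all_ambiguous_errors(self):
        with pytest.raises(ValueError):
            gc_fraction("NNN")

    def test_stratification_medians(self):
        # low-coverage target at GC 0.3, covered target at GC 0.8
        seqs = {"c": "ATTGCAATAG" + "GCGGCATCGG"}
        t = IntervalSet(
            [GenomicInterval("c", 0, 10), GenomicInterval("c", 10, 20)], merged=True
        )
        p = CoverageProfile(t, np.array([5] * 10 + [50] * 10))
        st_ = gc_stratification(p, seqs, 20)
        assert st_.median_insufficient == pytest.approx(0.3)
        assert st_.median_sufficient == pytest.approx(0.8)
        assert st_.applicable

    def test_empty_stratum_not_applicable(self):
        seqs = {"c": "ACGT" * 5}
        p = profile([50] * 20)
        st_ = gc_stratification(p, seqs, 20)
        assert not st_.applicable and np.isnan(st_.p_value)

    def test_null_case_no_signal(self, rng):
        # identical GC composition in both strata: expect a large p-value
        seqs = {"c": "ACGT" * 250}
        d = np.where(rng.random(1000) < 0.5, 5, 50)
        p = profile(d)
        st_ = gc_stratification(p, seqs, 20)
        assert st_.p_value >= 0.05


class TestPanelCoverage:
    def _panel(self, n_bases=30):
        txs = [
            TranscriptModel(f"t{i}", f"g{i}", "c", "+", [i * 100], [i * 100 + n_bases],
                            i * 100, i * 100 + n_bases)
            for i in range(2)
        ]
        return PanelDefinition(txs)

    def _profile_for(self, depths_by_tx):
        t = IntervalSet(
            [GenomicInterval("c", 0, 30), GenomicInterval("c", 100, 130)], merged=True
        )
        return CoverageProfile(t, np.concatenate(depths_by_tx))

    def test_fully_covered(self):
        p = self._profile_for([np.full(30, 25), np.full(30, 25)])
        res = panel_coverage(p, self._panel(), 20)
        assert res.fraction_fully_covered == 1.0

    def test_single_failing_base(self):
        d2 = np.full(30, 25)
        d2[7] = 3
        p = self._profile_for([np.full(30, 25), d2])
        res = panel_coverage(p, self._panel(), 20, q=0.95)
        assert res.fraction_fully_covered == 0.5
        assert res.fraction_q_covered == 1.0  # 29/30 > 0.95

    def test_q_one_equals_fully(self):
        d2 = np.full(30, 25)
        d2[7] = 3
        p = self._profile_for([np.full(30, 25), d2])
        res = panel_coverage(p, self._panel(), 20, q=1.0)
        assert res.fraction_q_covered == res.fraction_fully_covered

    def test_transcript_outside_targets_named(self):
        p = self._profile_for([np.full(30, 25), np.full(30, 25)])
        stray = TranscriptModel("tX", "gX", "c", "+", [500], [520], 500, 520)
        with pytest.raises(KeyError, match="tX"):
            panel_coverage(p, PanelDefinition([stray]), 20)
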