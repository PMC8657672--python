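"""Interval comparison and confusion-matrix metrics."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rlfscan import (
    ConfusionCounts,
    ParameterError,
    compute_metrics,
    confusion_by_region,
    infer_confusion_counts,
    intervals_to_index_set,
    overlap_stats,
)
from rlfscan.seqio import IntervalRecord


def iv(start, end, name="chr1", strand=None):
    return IntervalRecord(name, start, end, None, strand)


class TestIndexSet:
    def test_overlapping_intervals_merge(self):
        idx = intervals_to_index_set([iv(0, 3), iv(2, 5)])
        assert idx == {("chr1", p) for p in range(5)}

    def test_empty(self):
        assert intervals_to_index_set([]) == set()

    def test_disjoint_sizes_add(self):
        assert len(intervals_to_index_set([iv(0, 2), iv(5, 6)])) == 3

    def test_idempotent_and_order_independent(self):
        a = [iv(0, 10), iv(5, 15), iv(30, 40)]
        fwd = intervals_to_index_set(a)
        assert intervals_to_index_set(reversed(a)) == fwd
        assert intervals_to_index_set(a + a) == fwd

    def test_chromosomes_kept_apart(self):
        idx = intervals_to_index_set([iv(0, 5, "chr1"), iv(0, 5, "chr2")])
        assert len(idx) == 10


class TestOverlapStats:
    def test_identical_sets(self):
        s = intervals_to_index_set([iv(0, 10)])
        assert overlap_stats(s, s) == (1.0, 1.0, 1.0)

    def test_disjoint_sets(self):
        a = intervals_to_index_set([iv(0, 5)])
        b = intervals_to_index_set([iv(10, 15)])
        assert overlap_stats(a, b) == (0.0, 0.0, 0.0)

    def test_partial_overlap(self):
        a = intervals_to_index_set([iv(0, 10)])
        b = intervals_to_index_set([iv(5, 15)])
        assert overlap_stats(a, b) == (pytest.approx(5 / 15), 0.5, 0.5)

    def test_empty_denominators_are_nan(self):
        jac, fa, fb = overlap_stats(set(), set())
        assert all(math.isnan(v) for v in (jac, fa, fb))


class TestConfusionByRegion:
    def test_both_overlap_is_tp(self):
        c = confusion_by_region([iv(0, 100)], [iv(10, 20)], [iv(50, 60)])
        assert (c.tp, c.tn, c.fp, c.fn) == (1, 0, 0, 0)

    def test_nothing_anywhere_is_tn(self):
        c = confusion_by_region([iv(0, 100), iv(200, 300)], [], [])
        assert (c.tp, c.tn, c.fp, c.fn) == (0, 2, 0, 0)

    def test_four_canonical_cases(self):
        regions = [iv(0, 100), iv(100, 200), iv(200, 300), iv(300, 400)]
        reference = [iv(10, 20), iv(310, 320)]       # regions 0 and 3
        predicted = [iv(30, 40), iv(210, 220)]       # regions 0 and 2
        c = confusion_by_region(regions, reference, predicted)
        assert (c.tp, c.tn, c.fp, c.fn) == (1, 1, 1, 1)

    def test_overlapping_regions_rejected(self):
        with pytest.raises(ParameterError):
            confusion_by_region([iv(0, 100), iv(50, 150)], [], [])

    def test_strand_restriction(self):
        regions = [iv(0, 100)]
        ref = [iv(10, 20, strand="+")]
        pred = [iv(30, 40, strand="-")]
        c_plus = confusion_by_region(regions, ref, pred, strand="+")
        assert (c_plus.tp, c_plus.fn) == (0, 1)
        c_minus = confusion_by_region(regions, ref, pred, strand="-")
        assert (c_minus.fp, c_minus.tn) == (1, 0)


class TestComputeMetrics:
    def test_positive_strand_benchmark_row(self):
        """Counts (1,10,0,3) give accuracy 78.57%, sens 25%, spec 100%,
        MCC 0.44; NPV (not PPV) reproduces the published 76.92%."""
        m = compute_metrics(ConfusionCounts(tp=1, tn=10, fp=0, fn=3))
        pct = m.as_percentages()
        assert pct["accuracy_percent"] == 78.57
        assert pct["sensitivity_percent"] == 25.0
        assert pct["specificity_percent"] == 100.0
        assert pct["mcc"] == 0.44
        assert pct["npv_percent"] == 76.92
        assert pct["ppv_percent"] == 100.0

    def test_negative_strand_benchmark_row(self):
        m = compute_metrics(ConfusionCounts(tp=2, tn=7, fp=2, fn=3))
        pct = m.as_percentages()
        assert pct["accuracy_percent"] == 64.29
        assert pct["sensitivity_percent"] == 40.0
        assert pct["specificity_percent"] == 77.78
        assert pct["mcc"] == 0.19
        assert pct["npv_percent"] == 70.0
        assert pct["ppv_percent"] == 50.0

    def test_perfect_prediction(self):
        m = compute_metrics(ConfusionCounts(5, 5, 0, 0))
        assert m.accuracy == m.sensitivity == m.specificity == 1.0
        assert m.mcc == 1.0

    def test_undefined_denominators_are_nan_not_zero(self):
        m = compute_metrics(ConfusionCounts(tp=0, tn=5, fp=0, fn=0))
        assert math.isnan(m.sensitivity)
        assert math.isnan(m.ppv)
        assert math.isnan(m.mcc)

    counts = st.integers(min_value=0, max_value=30)

    @settings(derandomize=True, max_examples=200)
    @given(counts, counts, counts, counts)
    def test_mcc_bounds_and_label_swap(self, tp, tn, fp, fn):
        if tp + tn + fp + fn == 0:
            return
        m = compute_metrics(ConfusionCounts(tp, tn, fp, fn))
        if math.isfinite(m.mcc):
            assert -1.0 - 1e-12 <= m.mcc <= 1.0 + 1e-12
            if tp > 0 and tn > 0 and fp == 0 and fn == 0:
                assert m.mcc == 1.0
            # inverting the predicted labels negates MCC
            swapped = compute_metrics(ConfusionCounts(fn, fp, tn, tp))
            if math.isfinite(swapped.mcc):
                assert swapped.mcc == pytest.approx(-m.mcc)


class TestInferConfusionCounts:
    def test_recovers_known_counts(self):
        matches = infer_confusion_counts(14, 78.57, 25.0, 100.0)
        assert matches == [ConfusionCounts(tp=1, tn=10, fp=0, fn=3)]

    def test_impossible_rates_have_no_solution(self):
        assert infer_confusion_counts(5, 99.99, 1.0, 1.0) == []
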