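"""Interval comparison and confusion-matrix validation.

Predicted R-loop calls are compared with an experimental reference (e.g.
DRIPc/RDIP peaks) in two complementary ways:

* nucleotide-level: intervals are flattened to index sets (every base inside
  any call, strand-blind) and compared with Jaccard/containment fractions;
* region-level: for caller-supplied evaluation regions (e.g. one per gene),
  each region is classified TP / TN / FP / FN according to whether the
  reference and/or the prediction overlap it at all, and standard metrics
  including the Matthews correlation coefficient are derived.

Undefined ratios (zero denominators) are reported as NaN, never as 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import product
from typing import Iterable, Sequence

from .errors import FormatError, ParameterError
from .seqio import IntervalRecord

NAN = float("nan")


def intervals_to_index_set(
        intervals: Iterable[IntervalRecord]) -> set[tuple[str, int]]:
    """Flatten intervals to the set of (seq_name, position) pairs they cover.

    Overlaps merge naturally (it is a set union); strand is ignored.
    """
    positions: set[tuple[str, int]] = set()
    for rec in intervals:
        positions.update((rec.seq_name, p) for p in range(rec.start, rec.end))
    return positions


def overlap_stats(a: set, b: set) -> tuple[float, float, float]:
    """(Jaccard, |a∩b|/|a|, |a∩b|/|b|); NaN where the denominator is empty."""
    inter = len(a & b)
    union = len(a | b)
    return (
        inter / union if union else NAN,
        inter / len(a) if a else NAN,
        inter / len(b) if b else NAN,
    )


@dataclass(frozen=True)
class ConfusionCounts:
    """Region-level confusion matrix."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ParameterError("confusion counts must be nonnegative")

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class MetricsReport:
    """Derived classification metrics, as fractions (MCC in [-1, 1]).

    ``ppv`` is precision TP/(TP+FP); ``npv`` is TN/(TN+FN).  Both are
    reported because published per-strand benchmark tables in this area have
    labelled NPV as "Precision" (see docs/methods.md).
    """

    accuracy: float
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    mcc: float

    def as_percentages(self) -> dict:
        """Percentages rounded to 2 decimals; MCC rounded to 2 decimals."""
        def pct(x: float) -> float:
            return round(100 * x, 2) if math.isfinite(x) else NAN

        return {
            "accuracy_percent": pct(self.accuracy),
            "sensitivity_percent": pct(self.sensitivity),
            "specificity_percent": pct(self.specificity),
            "ppv_percent": pct(self.ppv),
            "npv_percent": pct(self.npv),
            "mcc": round(self.mcc, 2) if math.isfinite(self.mcc) else NAN,
        }


def _overlaps_any(region: IntervalRecord,
                  calls: Sequence[IntervalRecord]) -> bool:
    return any(c.seq_name == region.seq_name
               and c.start < region.end and c.end > region.start
               for c in calls)


def confusion_by_region(regions: Sequence[IntervalRecord],
                        reference: Sequence[IntervalRecord],
                        predicted: Sequence[IntervalRecord],
                        strand: str | None = None) -> ConfusionCounts:
    """Classify each evaluation region by reference/prediction overlap.

    TP: both overlap the region; TN: neither; FP: prediction only;
    FN: reference only.  ``strand`` restricts both call sets to one strand
    (records without strand annotation always pass).  Regions must not
    overlap each other within a sequence.
    """
    by_name: dict[str, list[IntervalRecord]] = {}
    for r in regions:
        if r.start >= r.end:
            raise FormatError(f"region start {r.start} >= end {r.end}")
        by_name.setdefault(r.seq_name, []).append(r)
    for group in by_name.values():
        group.sort(key=lambda r: r.start)
        for prev, cur in zip(group, group[1:]):
            if cur.start < prev.end:
                raise ParameterError(
                    f"evaluation regions overlap on {cur.seq_name!r}")

    if strand is not None:
        reference = [r for r in reference
                     if r.strand in (None, ".", strand)]
        predicted = [p for p in predicted
                     if p.strand in (None, ".", strand)]

    tp = tn = fp = fn = 0
    for region in regions:
        has_ref = _overlaps_any(region, reference)
        has_pred = _overlaps_any(region, predicted)
        if has_ref and has_pred:
            tp += 1
        elif not has_ref and not has_pred:
            tn += 1
        elif has_pred:
            fp += 1
        else:
            fn += 1
    return ConfusionCounts(tp, tn, fp, fn)


def _ratio(num: float, den: float) -> float:
    return num / den if den else NAN


def compute_metrics(c: ConfusionCounts) -> MetricsReport:
    """Accuracy, sensitivity, specificity, PPV, NPV and MCC from counts."""
    if c.n < 1:
        raise ParameterError("at least one evaluated region is required")
    mcc_den = math.sqrt(float((c.tp + c.fp) * (c.tp + c.fn)
                              * (c.tn + c.fp) * (c.tn + c.fn)))
    return MetricsReport(
        accuracy=_ratio(c.tp + c.tn, c.n),
        sensitivity=_ratio(c.tp, c.tp + c.fn),
        specificity=_ratio(c.tn, c.tn + c.fp),
        ppv=_ratio(c.tp, c.tp + c.fp),
        npv=_ratio(c.tn, c.tn + c.fn),
        mcc=_ratio(c.tp * c.tn - c.fp * c.fn, mcc_den),
    )


def infer_confusion_counts(n: int, accuracy_percent: float,
                           sensitivity_percent: float,
                           specificity_percent: float,
                           decimals: int = 2) -> list[ConfusionCounts]:
    """All confusion matrices over ``n`` regions matching printed rates.

    Exhaustively enumerates nonnegative (tp, fn, fp, tn) summing to ``n``
    and keeps those whose accuracy, sensitivity and specificity round (to
    ``decimals`` decimal places, as percentages) to the given printed
    values.  Lets a published metrics row be inverted back to its unique
    underlying counts when the counts themselves were not printed.
    """
    if n < 1:
        raise ParameterError("n must be >= 1")
    targets = (round(accuracy_percent, decimals),
               round(sensitivity_percent, decimals),
               round(specificity_percent, decimals))
    matches: list[ConfusionCounts] = []
    for tp, fn, fp in product(range(n + 1), repeat=3):
        tn = n - tp - fn - fp
        if tn < 0:
            continue
        m = compute_metrics(ConfusionCounts(tp, tn, fp, fn))
        got = (m.accuracy, m.sensitivity, m.specificity)
        if any(not math.isfinite(v) for v in got):
            continue
        if tuple(round(100 * v, decimals) for v in got) == targets:
            matches.append(ConfusionCounts(tp, tn, fp, fn))
    return matches
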