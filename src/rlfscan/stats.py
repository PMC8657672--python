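"""Per-analysis summary statistics: hit counts, R-loop rate, CG content and
the positional heat map.

The R-loop rate is hits per kilobase of analyzed sequence.  Coverage uses
union semantics: a position inside several overlapping hits counts once.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .errors import ParameterError
from .models import GenomicSequence, RLFSHit


@dataclass(frozen=True)
class BinValue:
    """One heat-map bin: overlapping-hit count and covered fraction."""

    bin_start: int
    bin_end: int
    count: int
    coverage: float


@dataclass(frozen=True)
class SummaryReport:
    seq_name: str
    seq_length: int
    n_hits: int
    rloop_rate: float  # hits per kilobase
    covered_fraction: float
    cg_content: float
    heatmap: tuple[BinValue, ...]

    def to_dict(self) -> dict:
        return {
            "seq_name": self.seq_name,
            "seq_length": self.seq_length,
            "n_hits": self.n_hits,
            "rloop_rate_per_kb": round(self.rloop_rate, 4),
            "covered_percent": round(100 * self.covered_fraction, 2),
            "cg_percent": round(100 * self.cg_content, 2),
        }


def cg_content(residues: str) -> float:
    """(C + G) / length over the whole sequence."""
    if not residues:
        raise ParameterError("cg_content of an empty sequence is undefined")
    return (residues.count("C") + residues.count("G")) / len(residues)


def _merged_intervals(hits: Sequence[RLFSHit]) -> list[tuple[int, int]]:
    spans = sorted((h.start, h.end) for h in hits)
    merged: list[tuple[int, int]] = []
    for s, e in spans:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def covered_positions(hits: Sequence[RLFSHit]) -> int:
    """Size of the union of hit intervals (strand-blind)."""
    return sum(e - s for s, e in _merged_intervals(hits))


def heatmap(hits: Sequence[RLFSHit], seq_length: int, n_bins: int = 100,
            mode: str = "count") -> list[BinValue]:
    """Equal-width positional bins (the last absorbs the remainder).

    ``count`` is the number of hits overlapping the bin by >= 1 nt;
    ``coverage`` the unioned covered fraction of the bin.  Both fields are
    always populated; ``mode`` selects which one renderers should display.
    """
    if mode not in ("count", "coverage"):
        raise ParameterError(f"unknown heatmap mode {mode!r}")
    if n_bins < 1:
        raise ParameterError("n_bins must be >= 1")
    if seq_length < n_bins:
        raise ParameterError("n_bins may not exceed the sequence length")
    width = seq_length // n_bins
    edges = [i * width for i in range(n_bins)] + [seq_length]
    merged = _merged_intervals(hits)
    bins: list[BinValue] = []
    for i in range(n_bins):
        lo, hi = edges[i], edges[i + 1]
        count = sum(1 for h in hits if h.start < hi and h.end > lo)
        covered = sum(min(e, hi) - max(s, lo)
                      for s, e in merged if s < hi and e > lo)
        bins.append(BinValue(lo, hi, count, covered / (hi - lo)))
    return bins


def summarize(seq: GenomicSequence, hits: Sequence[RLFSHit],
              n_bins: int = 100) -> SummaryReport:
    """Assemble the full per-sequence summary."""
    n = seq.length
    if n == 0:
        raise ParameterError("cannot summarize an empty sequence")
    bins = heatmap(hits, n, min(n_bins, n))
    return SummaryReport(
        seq_name=seq.name,
        seq_length=n,
        n_hits=len(hits),
        rloop_rate=len(hits) / (n / 1000),
        covered_fraction=covered_positions(hits) / n,
        cg_content=cg_content(seq.residues),
        heatmap=tuple(bins),
    )


def format_summary(report: SummaryReport) -> str:
    """Human-readable text block for one sequence."""
    d = report.to_dict()
    lines = [
        f"sequence        {d['seq_name']}",
        f"length          {d['seq_length']} nt",
        f"R-loops found   {d['n_hits']}",
        f"R-loop rate     {d['rloop_rate_per_kb']} per kb",
        f"covered         {d['covered_percent']}%",
        f"CG content      {d['cg_percent']}%",
    ]
    return "\n".join(lines)
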