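"""Sequence and interval I/O.

Readers accept either a filesystem path or already-loaded text (a string
containing a newline, or starting with ``>`` for FASTA, is treated as text).
Writers accept a path or an open text handle.

Coordinate conventions follow genome-browser habits: BED and bedGraph are
0-based half-open; the CSV result table is 1-based inclusive (human-facing).
"""

from __future__ import annotations

import csv
import os
from dataclasses import dataclass
from math import isfinite
from typing import Iterable, Sequence, TextIO

from .core import normalize_residues
from .errors import FormatError, ParameterError
from .models import GenomicSequence, RLFSHit

_BED_SKIP_PREFIXES = ("#", "track", "browser")


@dataclass(frozen=True)
class IntervalRecord:
    """A BED-like interval: 0-based half-open, optional score and strand."""

    seq_name: str
    start: int
    end: int
    value: float | None = None
    strand: str | None = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise FormatError(
                f"interval start {self.start} >= end {self.end}")
        if self.value is not None and not isfinite(self.value):
            raise FormatError(f"non-finite interval value {self.value!r}")


def _looks_like_text(source) -> bool:
    return isinstance(source, str) and ("\n" in source or
                                        source.startswith(">"))


def _as_lines(source) -> list[str]:
    if hasattr(source, "read"):
        return source.read().splitlines()
    if _looks_like_text(source):
        return source.splitlines()
    with open(os.fspath(source), "r", encoding="utf-8") as fh:
        return fh.read().splitlines()


def read_fasta(source) -> list[GenomicSequence]:
    """Parse (multi-record) FASTA into :class:`GenomicSequence` records.

    Residue lines are concatenated, uppercased and U-mapped to T; characters
    outside {A,C,G,T,N,U} raise :class:`FormatError` naming the line.
    """
    lines = _as_lines(source)
    records: list[GenomicSequence] = []
    name: str | None = None
    desc = ""
    parts: list[str] = []
    header_line = 0

    def flush() -> None:
        if name is None:
            return
        residues = "".join(parts)
        if not residues:
            raise FormatError(f"record {name!r} has no sequence",
                              line=header_line)
        records.append(GenomicSequence(name, residues, desc))

    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith(">"):
            flush()
            fields = line[1:].split(maxsplit=1)
            if not fields:
                raise FormatError("empty FASTA header", line=lineno)
            name, desc = fields[0], fields[1] if len(fields) > 1 else ""
            header_line = lineno
            parts = []
        else:
            if name is None:
                raise FormatError(
                    "sequence data before any '>' header "
                    "(use read_plain for headerless input)", line=lineno)
            parts.append(normalize_residues(line.replace(" ", ""),
                                            line=lineno))
    flush()
    if not records:
        raise FormatError("no FASTA records found")
    return records


def read_plain(text: str, name: str = "sequence") -> GenomicSequence:
    """Read a bare sequence pasted as plain text.

    Whitespace and digits are stripped so numbered listings copied from a
    viewer parse cleanly.
    """
    cleaned = "".join(c for c in text if not (c.isspace() or c.isdigit()))
    if not cleaned:
        raise FormatError("no sequence characters found in plain-text input")
    return GenomicSequence(name, normalize_residues(cleaned))


def _open_dest(destination) -> tuple[TextIO, bool]:
    if hasattr(destination, "write"):
        return destination, False
    return open(os.fspath(destination), "w", encoding="utf-8",
                newline=""), True


CSV_COLUMNS = [
    "seq_name", "start", "end", "length", "model", "strand",
    "riz_sequence", "riz_g_percent", "linker_length",
    "rez_sequence", "rez_g_percent", "g3", "g4", "g5", "score",
]


def hit_to_row(hit: RLFSHit) -> dict:
    """CSV row for one hit (1-based inclusive coordinates, % densities)."""
    return {
        "seq_name": hit.seq_name,
        "start": hit.start + 1,
        "end": hit.end,
        "length": hit.length,
        "model": hit.model_id,
        "strand": hit.strand,
        "riz_sequence": hit.riz.sequence,
        "riz_g_percent": f"{100 * hit.riz.g_density:.2f}",
        "linker_length": hit.linker_len,
        "rez_sequence": hit.rez.sequence,
        "rez_g_percent": f"{100 * hit.rez.g_density:.2f}",
        "g3": hit.components.g3,
        "g4": hit.components.g4,
        "g5": hit.components.g5,
        "score": f"{hit.score:.4f}",
    }


def _meta_lines(meta) -> list[str]:
    if not meta:
        return []
    return [f"# {key}={value}" for key, value in meta.items()]


def write_csv(hits: Sequence[RLFSHit], destination, meta=None) -> int:
    """Write the per-hit result table; returns the number of data rows.

    Optional ``meta`` (mapping) is emitted as ``# key=value`` provenance
    lines before the header.
    """
    rows = sorted(hits, key=lambda h: (h.seq_name, *h.key()))
    fh, owned = _open_dest(destination)
    try:
        for line in _meta_lines(meta):
            fh.write(line + "\n")
        writer = csv.DictWriter(fh, fieldnames=CSV_COLUMNS,
                                lineterminator="\n")
        writer.writeheader()
        for hit in rows:
            writer.writerow(hit_to_row(hit))
    finally:
        if owned:
            fh.close()
    return len(rows)


def write_bedgraph(hits: Sequence[RLFSHit], meta, destination,
                   track_name: str = "rlfs") -> int:
    """Write hits as a bedGraph track (0-based half-open, tab-separated).

    ``meta`` is a mapping describing the analysis; it becomes ``#`` comment
    lines plus the track line's description.  Records are sorted by
    (seq_name, start).
    """
    rows = sorted(hits, key=lambda h: (h.seq_name, *h.key()))
    desc = " ".join(f"{k}={v}" for k, v in (meta or {}).items())
    fh, owned = _open_dest(destination)
    try:
        for line in _meta_lines(meta):
            fh.write(line + "\n")
        fh.write(f'track type=bedGraph name="{track_name}" '
                 f'description="{desc}"\n')
        for hit in rows:
            fh.write(f"{hit.seq_name}\t{hit.start}\t{hit.end}\t"
                     f"{hit.score:g}\n")
    finally:
        if owned:
            fh.close()
    return len(rows)


def read_bed(source) -> list[IntervalRecord]:
    """Parse BED 3-6 (and bedGraph) into :class:`IntervalRecord` lists.

    Comment/track/browser lines are skipped.  A numeric 4th column (bedGraph)
    or 5th column (BED score) becomes ``value``; a 6th column in {+,-,.}
    becomes ``strand``.
    """
    lines = _as_lines(source)
    records: list[IntervalRecord] = []
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line.startswith(_BED_SKIP_PREFIXES):
            continue
        cols = line.split()
        if len(cols) < 3:
            raise FormatError("expected at least 3 columns", line=lineno)
        try:
            start, end = int(cols[1]), int(cols[2])
        except ValueError:
            raise FormatError(
                f"non-integer coordinates {cols[1]!r}/{cols[2]!r}",
                line=lineno) from None
        if start >= end:
            raise FormatError(f"start {start} >= end {end}", line=lineno)
        value = None
        strand = None
        if len(cols) == 4:
            try:
                value = float(cols[3])
            except ValueError:
                value = None  # BED name column, ignored
        elif len(cols) >= 5:
            try:
                value = float(cols[4])
            except ValueError:
                value = None
            if len(cols) >= 6 and cols[5] in ("+", "-", "."):
                strand = cols[5]
        records.append(IntervalRecord(cols[0], start, end, value, strand))
    return records


def write_fasta(seqs: Iterable[GenomicSequence], destination,
                width: int = 60) -> None:
    """Write sequences in wrapped FASTA."""
    if width < 1:
        raise ParameterError("width must be >= 1")
    fh, owned = _open_dest(destination)
    try:
        for seq in seqs:
            header = f">{seq.name}"
            if seq.description:
                header += f" {seq.description}"
            fh.write(header + "\n")
            for i in range(0, len(seq.residues), width):
                fh.write(seq.residues[i:i + width] + "\n")
    finally:
        if owned:
            fh.close()


def write_intervals_bed(intervals: Sequence[IntervalRecord],
                        destination) -> int:
    """Write intervals as BED (name '.', score, strand when present)."""
    fh, owned = _open_dest(destination)
    try:
        for rec in sorted(intervals, key=lambda r: (r.seq_name, r.start)):
            cols = [rec.seq_name, str(rec.start), str(rec.end), ".",
                    "0" if rec.value is None else f"{rec.value:g}",
                    rec.strand or "."]
            fh.write("\t".join(cols) + "\n")
    finally:
        if owned:
            fh.close()
    return len(intervals)
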