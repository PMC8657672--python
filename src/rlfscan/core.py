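"""RLFS detection on both DNA strands.

The scan works in the 5'->3' orientation of each strand.  For the (+) strand
the input residues are scanned directly; for the (-) strand the reverse
complement is scanned and all resulting coordinates are mapped back into
input(+) frame.  Detection is deterministic: output order is fixed by
(start, strand, model).

Density thresholds are compared with a 1e-9 slack in favour of the sequence
(``g_count >= threshold * length - 1e-9``) so exact rational boundaries such
as 2/5 vs 0.4 are not lost to binary floating point.
"""

from __future__ import annotations

import itertools
import re
from typing import Iterable, Iterator, Sequence

from .errors import FormatError, ParameterError
from .models import (
    DEFAULT_MODELS,
    GCluster,
    GenomicSequence,
    ModelParams,
    REZ,
    RIZ,
    RLFSHit,
    ScoreComponents,
)

_EPS = 1e-9

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

_NORMALIZE = str.maketrans("acgtnuU", "ACGTNTT")
_VALID_RE = re.compile(r"[^ACGTN]")


def normalize_residues(raw: str, *, line: int | None = None) -> str:
    """Uppercase, map U->T and validate the alphabet.

    Raises :class:`FormatError` (carrying ``line`` when given) on characters
    outside {A,C,G,T,N,U}.
    """
    residues = raw.translate(_NORMALIZE)
    bad = _VALID_RE.search(residues)
    if bad:
        raise FormatError(
            f"illegal character {bad.group()!r} in sequence "
            "(expected A/C/G/T/N/U)", line=line)
    return residues


def reverse_complement(residues: str) -> str:
    """Watson-Crick reverse complement; N pairs with N."""
    bad = _VALID_RE.search(residues)
    if bad:
        raise FormatError(f"unexpected character {bad.group()!r}")
    return residues.translate(_COMPLEMENT)[::-1]


def map_to_plus(start: int, end: int, seq_len: int) -> tuple[int, int]:
    """Map a half-open interval from (-)-scan coordinates to input(+) frame."""
    if not 0 <= start < end <= seq_len:
        raise ParameterError(
            f"invalid interval ({start}, {end}) for length {seq_len}")
    return seq_len - end, seq_len - start


def find_g_clusters(residues: str, min_len: int) -> list[GCluster]:
    """All maximal runs of >= ``min_len`` consecutive G, in start order."""
    if min_len < 1:
        raise ParameterError("min_len must be >= 1")
    return [GCluster(m.start(), m.end())
            for m in re.finditer("G{%d,}" % min_len, residues)]


def g_density(residues: str) -> float:
    """Fraction of G over the whole string (N counts in the denominator)."""
    if not residues:
        raise ParameterError("g_density of an empty string is undefined")
    return residues.count("G") / len(residues)


def _density_ok(g_count: int, length: int, threshold: float) -> bool:
    return g_count >= threshold * length - _EPS


def _g_prefix(residues: str) -> list[int]:
    """prefix[i] = number of G among residues[:i]."""
    return [0, *itertools.accumulate(1 if c == "G" else 0 for c in residues)]


def find_riz(residues: str, params: ModelParams,
             _prefix: list[int] | None = None) -> list[RIZ]:
    """Enumerate RIZ candidates: one per qualifying G-tract start.

    From each tract the chain of following tracts reachable through gaps of
    at most ``max_intra_riz_gap`` nt is walked, and the longest extension
    meeting the tract-count and G-density constraints is emitted (the density
    constraint is not monotone in the span, so every chain end is checked).
    """
    tracts = find_g_clusters(residues, params.min_tract_len)
    prefix = _prefix if _prefix is not None else _g_prefix(residues)
    out: list[RIZ] = []
    for i, first in enumerate(tracts):
        best_j: int | None = None
        j = i
        while True:
            if j - i + 1 >= params.min_tract_count:
                span = tracts[j].end - first.start
                g = prefix[tracts[j].end] - prefix[first.start]
                if _density_ok(g, span, params.min_riz_g_density):
                    best_j = j
            if (j + 1 < len(tracts)
                    and tracts[j + 1].start - tracts[j].end
                    <= params.max_intra_riz_gap):
                j += 1
            else:
                break
        if best_j is not None:
            end = tracts[best_j].end
            span = end - first.start
            g = prefix[end] - prefix[first.start]
            out.append(RIZ(
                start=first.start,
                end=end,
                sequence=residues[first.start:end],
                g_density=g / span,
                tracts=tuple(tracts[i:best_j + 1]),
                model_id=params.model_id,
            ))
    return out


def _rez_lengths(avail: int, params: ModelParams) -> Iterator[int]:
    """Candidate REZ window lengths: the step ladder, plus the window clipped
    flush with the sequence end when that still meets the minimum length."""
    length = params.min_rez_len
    longest_full = 0
    while length <= avail and length <= params.max_rez_len:
        yield length
        longest_full = length
        length += params.rez_step
    clipped = min(avail, params.max_rez_len)
    if clipped >= params.min_rez_len and clipped != longest_full:
        yield clipped


def find_rez(residues: str, search_from: int, params: ModelParams,
             _prefix: list[int] | None = None) -> tuple[int, REZ] | None:
    """Locate the REZ paired with a RIZ ending at ``search_from``.

    Candidate REZs start at a G within ``max_linker_len`` nt of
    ``search_from`` and span a ladder window trimmed back to its last G.
    Among candidates meeting the length and G-density constraints the one
    maximizing (trimmed) REZ length wins, ties broken by the smaller linker,
    then the smaller start.  Returns ``(linker_len, REZ)`` or ``None``.
    """
    n = len(residues)
    if not 0 <= search_from <= n:
        raise ParameterError("search_from outside the sequence")
    prefix = _prefix if _prefix is not None else _g_prefix(residues)
    best: tuple[int, int, int] | None = None  # (trimmed_len, start, end)
    stop = min(search_from + params.max_linker_len, n - 1)
    for p in range(search_from, stop + 1):
        if residues[p] != "G":
            continue
        for length in _rez_lengths(n - p, params):
            g = prefix[p + length] - prefix[p]
            if not _density_ok(g, length, params.min_rez_g_density):
                continue
            end = p + length
            while residues[end - 1] != "G":
                end -= 1
            trimmed = end - p
            if trimmed < params.min_rez_len:
                continue
            if best is None or trimmed > best[0] or (
                    trimmed == best[0] and p < best[1]):
                best = (trimmed, p, end)
    if best is None:
        return None
    _, p, end = best
    g = prefix[end] - prefix[p]
    rez = REZ(start=p, end=end, sequence=residues[p:end],
              g_density=g / (end - p))
    return p - search_from, rez


def compute_score(components: ScoreComponents) -> float:
    """RLFS score: (g3 + 2*g4 + 3*g5) * RIZ_G% * RLOOP_G% (densities as
    fractions)."""
    weight = components.g3 + 2 * components.g4 + 3 * components.g5
    return weight * components.riz_g * components.rloop_g


def score_components(span_residues: str, riz_len: int) -> ScoreComponents:
    """Cluster counts and densities over one RLFS span (scan orientation).

    The span starts at the RIZ and ends at the REZ, so ``riz_len`` delimits
    the RIZ prefix for the RIZ density term.
    """
    g3 = g4 = g5 = 0
    for cluster in find_g_clusters(span_residues, 3):
        if cluster.length == 3:
            g3 += 1
        elif cluster.length == 4:
            g4 += 1
        else:
            g5 += 1
    return ScoreComponents(
        g3=g3, g4=g4, g5=g5,
        riz_g=g_density(span_residues[:riz_len]),
        rloop_g=g_density(span_residues),
    )


def _resolve_models(models) -> list[ModelParams]:
    if isinstance(models, ModelParams):
        return [models]
    resolved = []
    for m in models:
        resolved.append(DEFAULT_MODELS[m] if isinstance(m, str) else m)
    if not resolved:
        raise ParameterError("at least one model must be selected")
    return sorted(resolved, key=lambda m: m.model_id)


def _resolve_strands(strands) -> list[str]:
    out = sorted(set(strands))
    if not out or not set(out) <= {"+", "-"}:
        raise ParameterError("strands must be a non-empty subset of {+, -}")
    return out


def detect_rlfs(seq: GenomicSequence,
                models: Iterable[ModelParams | str] | ModelParams = ("m1",),
                strands: Iterable[str] = ("+", "-")) -> list[RLFSHit]:
    """Detect RLFS hits on the selected strands of ``seq``.

    Each RIZ is paired with its REZ via :func:`find_rez`; RIZs without a REZ
    are dropped (an RLFS requires both zones).  Hits are reported in input(+)
    coordinates, sorted by (start, strand, model).
    """
    model_list = _resolve_models(models)
    strand_list = _resolve_strands(strands)
    n = len(seq.residues)
    hits: list[RLFSHit] = []
    for strand in strand_list:
        scan = seq.residues if strand == "+" else reverse_complement(
            seq.residues)
        prefix = _g_prefix(scan)
        for params in model_list:
            for riz in find_riz(scan, params, _prefix=prefix):
                found = find_rez(scan, riz.end, params, _prefix=prefix)
                if found is None:
                    continue
                linker_len, rez = found
                span = scan[riz.start:rez.end]
                comps = score_components(span, riz.length)
                hit = RLFSHit(
                    seq_name=seq.name,
                    strand=strand,
                    model_id=params.model_id,
                    start=riz.start,
                    end=rez.end,
                    riz=riz,
                    linker_len=linker_len,
                    rez=rez,
                    components=comps,
                    score=compute_score(comps),
                )
                if strand == "-":
                    hit = _hit_to_plus_frame(hit, n)
                hits.append(hit)
    hits.sort(key=RLFSHit.key)
    return hits


def _interval_to_plus(start: int, end: int, n: int) -> tuple[int, int]:
    return n - end, n - start


def _hit_to_plus_frame(hit: RLFSHit, n: int) -> RLFSHit:
    """Map a (-)-scan hit into input(+) coordinates (sequences untouched)."""
    start, end = map_to_plus(hit.start, hit.end, n)
    riz_s, riz_e = _interval_to_plus(hit.riz.start, hit.riz.end, n)
    rez_s, rez_e = _interval_to_plus(hit.rez.start, hit.rez.end, n)
    tracts = tuple(sorted(
        (GCluster(*_interval_to_plus(t.start, t.end, n))
         for t in hit.riz.tracts), key=lambda t: t.start))
    riz = RIZ(start=riz_s, end=riz_e, sequence=hit.riz.sequence,
              g_density=hit.riz.g_density, tracts=tracts,
              model_id=hit.riz.model_id)
    rez = REZ(start=rez_s, end=rez_e, sequence=hit.rez.sequence,
              g_density=hit.rez.g_density)
    return RLFSHit(seq_name=hit.seq_name, strand=hit.strand,
                   model_id=hit.model_id, start=start, end=end, riz=riz,
                   linker_len=hit.linker_len, rez=rez,
                   components=hit.components, score=hit.score)


def _shift_hit(hit: RLFSHit, offset: int) -> RLFSHit:
    if offset == 0:
        return hit
    riz = RIZ(start=hit.riz.start + offset, end=hit.riz.end + offset,
              sequence=hit.riz.sequence, g_density=hit.riz.g_density,
              tracts=tuple(GCluster(t.start + offset, t.end + offset)
                           for t in hit.riz.tracts),
              model_id=hit.riz.model_id)
    rez = REZ(start=hit.rez.start + offset, end=hit.rez.end + offset,
              sequence=hit.rez.sequence, g_density=hit.rez.g_density)
    return RLFSHit(seq_name=hit.seq_name, strand=hit.strand,
                   model_id=hit.model_id, start=hit.start + offset,
                   end=hit.end + offset, riz=riz, linker_len=hit.linker_len,
                   rez=rez, components=hit.components, score=hit.score)


def detect_chunked(seq_stream: Iterable[str],
                   chunk_len: int,
                   overlap: int,
                   models: Iterable[ModelParams | str] | ModelParams = ("m1",),
                   strands: Iterable[str] = ("+", "-"),
                   seq_name: str = "seq") -> list[RLFSHit]:
    """Detect RLFS over a streamed sequence, chunk by chunk.

    Chunks of ``chunk_len`` nt advance by ``chunk_len - overlap`` so that any
    hit whose RIZ span plus downstream reach (max_linker + max_rez) fits
    inside ``overlap`` is fully contained — with identical local context — in
    at least one chunk.  Hits touching a chunk edge (where context is
    truncated) are only accepted at the true sequence boundaries; duplicates
    across chunks are collapsed on (start, end, strand, model).  The result
    equals single-pass :func:`detect_rlfs` on the concatenated sequence.
    """
    model_list = _resolve_models(models)
    strand_list = _resolve_strands(strands)
    reach = {m.model_id: m.max_reach for m in model_list}
    min_overlap = max(m.max_reach + m.min_riz_span for m in model_list) + 1
    if overlap < min_overlap:
        raise ParameterError(
            f"overlap {overlap} too small: need >= {min_overlap} "
            "(max linker + max REZ + minimal RIZ + 1)")
    if chunk_len <= overlap:
        raise ParameterError("chunk_len must exceed overlap")

    stride = chunk_len - overlap
    buf = ""
    offset = 0
    first = True
    it = iter(seq_stream)
    exhausted = False
    seen: set[tuple] = set()
    out: list[RLFSHit] = []
    while True:
        while len(buf) < chunk_len and not exhausted:
            try:
                buf += normalize_residues(next(it))
            except StopIteration:
                exhausted = True
        window = buf[:chunk_len]
        is_last = exhausted and len(buf) <= chunk_len
        chunk_seq = GenomicSequence(seq_name, window)
        for hit in detect_rlfs(chunk_seq, model_list, strand_list):
            d = reach[hit.model_id]
            w = len(window)
            rs = hit.riz.start  # chunk-relative, plus frame
            re_ = hit.riz.end
            if hit.strand == "+":
                ok = ((rs >= 1 or first)
                      and (re_ + d <= w or is_last))
            else:
                # scan orientation of (-) runs right-to-left in plus frame
                ok = ((re_ <= w - 1 or is_last)
                      and (rs >= d or first))
            if not ok:
                continue
            shifted = _shift_hit(hit, offset)
            if shifted.key() not in seen:
                seen.add(shifted.key())
                out.append(shifted)
        if is_last:
            break
        buf = buf[stride:]
        offset += stride
        first = False
    out.sort(key=RLFSHit.key)
    return out


def merge_hits(hits: Sequence[RLFSHit]) -> list[dict]:
    """Collapse overlapping same-strand hits into merged regions.

    Returns dictionaries with seq_name, start, end, strand, n_hits and
    max_score, sorted by (seq_name, start, strand).  Used by the CLI
    ``--merge`` option and for region-level summaries.
    """
    groups: dict[tuple[str, str], list[RLFSHit]] = {}
    for h in hits:
        groups.setdefault((h.seq_name, h.strand), []).append(h)
    merged: list[dict] = []
    for (name, strand), group in groups.items():
        group.sort(key=lambda h: (h.start, h.end))
        cur = None
        for h in group:
            if cur is not None and h.start < cur["end"]:
                cur["end"] = max(cur["end"], h.end)
                cur["n_hits"] += 1
                cur["max_score"] = max(cur["max_score"], h.score)
            else:
                if cur is not None:
                    merged.append(cur)
                cur = {"seq_name": name, "start": h.start, "end": h.end,
                       "strand": strand, "n_hits": 1, "max_score": h.score}
        if cur is not None:
            merged.append(cur)
    merged.sort(key=lambda r: (r["seq_name"], r["start"], r["strand"]))
    return merged
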