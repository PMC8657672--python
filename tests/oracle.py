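"""Brute-force reference detector used to cross-check the scanner.

This re-derives the whole RLFS definition from first principles with plain
string scans and exhaustive candidate enumeration — no code is shared with
the package's detection path.  Hits are reported as comparable tuples:

    (start, end, strand, model_id, riz_start, riz_end, linker_len,
     rez_start, rez_end, g3, g4, g5, score)

with all coordinates in input(+) frame.  Density thresholds use the same
rational-boundary rule as the package contract:
g_count >= threshold * length - 1e-9.
"""

from itertools import accumulate

EPS = 1e-9

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def revcomp(residues: str) -> str:
    return "".join(_COMP[c] for c in reversed(residues))


def _g_runs(residues: str):
    """All maximal runs of G, by direct character scan."""
    runs = []
    i, n = 0, len(residues)
    while i < n:
        if residues[i] == "G":
            j = i
            while j < n and residues[j] == "G":
                j += 1
            runs.append((i, j))
            i = j
        else:
            i += 1
    return runs


def _dens_ok(g: int, length: int, thr: float) -> bool:
    return g >= thr * length - EPS


def scan_one_strand(residues: str, params):
    """All (riz, linker, rez) hits on one scanned strand, scan coordinates."""
    n = len(residues)
    prefix = [0, *accumulate(1 if c == "G" else 0 for c in residues)]

    def gc(s, e):
        return prefix[e] - prefix[s]

    tracts = [(s, e) for (s, e) in _g_runs(residues)
              if e - s >= params.min_tract_len]
    hits = []
    for a in range(len(tracts)):
        # enumerate every admissible chain end; keep the longest valid RIZ
        riz = None
        for b in range(a, len(tracts)):
            if b > a and (tracts[b][0] - tracts[b - 1][1]
                          > params.max_intra_riz_gap):
                break
            if b - a + 1 < params.min_tract_count:
                continue
            s, e = tracts[a][0], tracts[b][1]
            if _dens_ok(gc(s, e), e - s, params.min_riz_g_density):
                riz = (s, e)
        if riz is None:
            continue
        riz_s, riz_e = riz

        # exhaustive REZ candidate enumeration
        cands = []
        for p in range(riz_e,
                       min(riz_e + params.max_linker_len, n - 1) + 1):
            if residues[p] != "G":
                continue
            lengths = []
            L = params.min_rez_len
            while p + L <= n and L <= params.max_rez_len:
                lengths.append(L)
                L += params.rez_step
            clipped = min(n - p, params.max_rez_len)
            if clipped >= params.min_rez_len and clipped not in lengths:
                lengths.append(clipped)
            for L in lengths:
                if not _dens_ok(gc(p, p + L), L, params.min_rez_g_density):
                    continue
                q = p + L
                while residues[q - 1] != "G":
                    q -= 1
                if q - p >= params.min_rez_len:
                    cands.append((q - p, -p, p, q))
        if not cands:
            continue
        _, _, rez_s, rez_e = max(cands)

        # score over the full span
        span = residues[riz_s:rez_e]
        g3 = g4 = g5 = 0
        for (s, e) in _g_runs(span):
            size = e - s
            if size == 3:
                g3 += 1
            elif size == 4:
                g4 += 1
            elif size >= 5:
                g5 += 1
        riz_g = span[:riz_e - riz_s].count("G") / (riz_e - riz_s)
        rloop_g = span.count("G") / len(span)
        score = (g3 + 2 * g4 + 3 * g5) * riz_g * rloop_g
        hits.append((riz_s, riz_e, rez_s - riz_e, rez_s, rez_e,
                     g3, g4, g5, score))
    return hits


def detect(residues: str, models, strands=("+", "-")):
    """Full brute-force detection in input(+) frame, sorted like the
    package output."""
    n = len(residues)
    out = []
    for strand in strands:
        scan = residues if strand == "+" else revcomp(residues)
        for params in models:
            for (riz_s, riz_e, linker, rez_s, rez_e,
                 g3, g4, g5, score) in scan_one_strand(scan, params):
                if strand == "+":
                    tup = (riz_s, rez_e, "+", params.model_id,
                           riz_s, riz_e, linker, rez_s, rez_e,
                           g3, g4, g5, score)
                else:
                    tup = (n - rez_e, n - riz_s, "-", params.model_id,
                           n - riz_e, n - riz_s, linker,
                           n - rez_e, n - rez_s, g3, g4, g5, score)
                out.append(tup)
    out.sort(key=lambda t: t[:4])
    return out


def hit_tuple(hit):
    """Project a package RLFSHit onto the oracle's comparable tuple."""
    return (hit.start, hit.end, hit.strand, hit.model_id,
            hit.riz.start, hit.riz.end, hit.linker_len,
            hit.rez.start, hit.rez.end,
            hit.components.g3, hit.components.g4, hit.components.g5,
            hit.score)
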