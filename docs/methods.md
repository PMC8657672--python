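# Methods

## The RLFS model

An R-loop forming sequence is detected as three consecutive parts on one
strand, scanned 5'→3':

1. **RIZ** — a chain of maximal G-runs ("clusters"), each at least
   `min_tract_len` long, separated by gaps of 1–`max_intra_riz_gap` nt, with
   at least `min_tract_count` clusters and overall G-density
   ≥ `min_riz_g_density`.  The two shipped models differ only in the cluster
   geometry: m1 requires ≥ 3 clusters of ≥ 3 G, m2 requires ≥ 2 clusters of
   ≥ 4 G.
2. **Linker** — 0–`max_linker_len` nt between the RIZ end and the REZ start.
3. **REZ** — a G-flush window of `min_rez_len`–`max_rez_len` nt with
   G-density ≥ `min_rez_g_density`.

Both strands are scanned: the `-` strand as the reverse complement of the
input, with hit coordinates mapped back to the input frame.  Every hit gets
the score `(g3 + 2·g4 + 3·g5) · RIZ_G% · RLOOP_G%`, where g3/g4/g5 count
maximal G-clusters of size exactly 3, exactly 4 and ≥ 5 over the whole hit
span (so long clusters are never dropped), RIZ_G% is the G fraction of the
RIZ and RLOOP_G% of the whole span.  Counting over the full span (rather
than the RIZ alone) and bucketing ≥ 5 into g5 is this package's resolution
of an ambiguity in the published score description; both densities are kept
as fractions internally and rendered as percentages only at the CSV/report
layer.

## Default parameters

| parameter | default | meaning |
|---|---|---|
| `min_tract_len` / `min_tract_count` | 3 / 3 (m1), 4 / 2 (m2) | cluster geometry of the RIZ |
| `max_intra_riz_gap` | 10 nt | widest gap between RIZ clusters |
| `min_riz_g_density` | 0.50 | G fraction floor over the RIZ span |
| `max_linker_len` | 50 nt | widest RIZ–REZ spacer |
| `min_rez_len` / `max_rez_len` | 100 / 2000 nt | REZ length range |
| `min_rez_g_density` | 0.40 | G fraction floor over the REZ |
| `rez_step` | 100 nt | REZ greedy extension increment |

These mirror the defaults of the original quantitative RLFS model family
(QmRLFS) that this scanner's model definitions descend from; every value is
overridable per analysis.

## Exact search procedures

The published model family leaves the RIZ/REZ search procedures partly
open; the package fixes them as follows, and the test-suite's brute-force
oracle enumerates the same definitions exhaustively and independently.

**RIZ enumeration.**  One candidate per qualifying cluster start: from each
maximal G-run of sufficient length, the chain of following runs reachable
through admissible gaps is walked, and the *longest* chain end satisfying
the count and density constraints is emitted (density is not monotone in
the span, so every admissible end is checked).  Overlapping RIZs from
different starts are all reported — clustered, overlapping calls in G-rich
regions are intended behaviour; an optional merge collapses overlapping
same-strand hits for track export.

**REZ search.**  Candidate REZ starts are the G positions within
`max_linker_len` of the RIZ end (enumerating starts at G positions, rather
than trimming a leading non-G stretch afterwards, keeps the reported linker
within its bound by construction).  From each start the candidate lengths
are the ladder `min_rez_len + k·rez_step` capped at `max_rez_len`, plus the
window clipped flush with the sequence end when it still reaches
`min_rez_len`.  A window qualifies if its G-density meets the floor; it is
then trimmed back to its last G and must still reach `min_rez_len`.  Among
qualifying candidates the maximal trimmed length wins; ties prefer the
smaller linker, then the smaller start.  One REZ per RIZ; a RIZ without a
REZ is not a hit.

**Numerical choices.**  Density thresholds are compared as
`g_count ≥ threshold·length − 1e−9`, so exact rational boundaries (2/5
against a 0.4 floor) are decided in favour of the sequence rather than lost
to binary floating point.  Detection involves no randomness; output order
is fixed by (start, strand, model).  N is never G, may appear in gaps,
linkers and REZ interiors, and counts in density denominators.  Lowercase
(soft-masked) input is uppercased, U maps to T, and anything outside
{A,C,G,T,N,U} is rejected with the offending line.

## Chunked scanning

Long sequences are scanned in chunks of `chunk_len` advancing by
`chunk_len − overlap`.  A hit is accepted from a chunk only where its local
context is complete: its RIZ must not touch the chunk's scan-upstream edge
(unless that edge is the true sequence boundary) and there must be at least
`max_linker_len + max_rez_len` nt of chunk beyond the RIZ end (again unless
the chunk reaches the true boundary).  Any hit whose RIZ span plus that
reach fits inside `overlap` is therefore seen, with full context, by at
least one chunk; duplicates are collapsed on (start, end, strand, model).
The default overlap of 3000 nt covers RIZ spans up to ~950 nt under default
parameters; a pathological RIZ chain longer than that could in principle be
missed in chunked mode, which is why `overlap` is validated against
`max_linker + max_rez + minimal RIZ + 1` and configurable.  Equivalence
with single-pass detection is asserted by the test suite on fixtures with
motifs planted across chunk boundaries.

## Validation machinery

Nucleotide-level comparison flattens interval sets to sets of
(sequence, position) pairs — strand-blind, because the experimental
references it is meant for do not resolve R-loop direction — and reports
Jaccard plus both containment fractions.  Region-level validation takes
caller-supplied, non-overlapping evaluation regions (e.g. one per gene; no
default window size is invented) and classifies each as TP/TN/FP/FN by
whether reference and/or prediction overlap it at all, then derives
accuracy, sensitivity, specificity, PPV, NPV and MCC, with undefined ratios
reported as NaN, never 0.

Both PPV and NPV are always reported.  Published per-strand benchmark rows
for this model family print a "Precision" column whose values (76.92%, 70%)
match TN/(TN+FN) — NPV — rather than TP/(TP+FP); `infer_confusion_counts`
makes this checkable: exhaustive enumeration over all confusion matrices on
the 14-region panel shows exactly one matrix per strand reproduces the
printed accuracy/sensitivity/specificity, and on those matrices NPV (not
PPV) equals the printed precision while the printed MCC (0.44 / 0.19) is
reproduced exactly.  Rounding follows the printed presentation: percentages
and MCC to 2 decimals.

## Synthetic data

The generator emulates the *signature*, not the biology: i.i.d. backgrounds
with a chosen G fraction (default 0.25; 0.10 in "low-G" recovery fixtures
so motif signal stands apart from chance G-runs), with model-conformant
motifs spliced in at known coordinates (validated against their model at
generation time, ≥ 3 kb apart so chunk tests are unambiguous, random strand
and model mix).  Two construction details keep ground truth unambiguous:
planted REZs reach their G-density with GG dinucleotides only (no run ≥ 3,
so a REZ can never seed a second RIZ), and the default 20-nt G-free linker
exceeds the maximal intra-RIZ gap (so the RIZ cannot extend into the REZ).
Default planted geometry: minimal cluster counts, 1-nt gaps, 200-nt REZ at
G-density 0.55.

What the fixtures do **not** emulate: real genomic base composition
(isochores, CpG islands, repeats), transcriptional context, or read-level
experimental noise — DRIP-style data is represented only as interval files.
Passing tests therefore demonstrate algorithmic correctness (agreement with
the exhaustive definition, strand symmetry, chunk invariance, format
contracts), not predictive accuracy on real chromatin.

A note on "0%-G" fixtures: a background without G on the input strand still
contains C, which is G on the complementary strand.  Fixtures that must be
signature-free on *both* strands (exact hit/truth identity checks) set the
C fraction to 0 as well, leaving an A/T background.

## Problem sizes and determinism

The bundled checks run at desk scale, chosen to finish in seconds while
exercising every code path: 1000 random sequences of 0.1–2 kb for oracle
equivalence and strand symmetry, 100 planted motifs for recovery, ten 10-kb
fixtures for chunk equivalence.  All randomness flows through seeded
`numpy` generators; the acceptance script derives every sub-seed from its
`--seed` argument.

## Known limitations

* The detector is purely sequence-based: no thermodynamics or supercoiling,
  no RNA input, no probabilistic scoring beyond the cluster/density score.
* One REZ per RIZ (the maximizer defined above); alternative downstream
  windows are not reported.
* Chunked mode can miss hits whose RIZ span exceeds
  `overlap − (max_linker + max_rez)`; raise `overlap` for exotic parameter
  sets.
* Region-level metrics depend entirely on the caller's region definitions;
  the package deliberately supplies no default segmentation.
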