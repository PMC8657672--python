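"""Optional: compare scanner output with experimental R-loop calls for a
real gene you download yourself.

Supply a gene sequence in FASTA (e.g. the first 6 kb of human NEAT1) and a
BED file of experimental calls (DRIPc/RDIP peaks, genome-browser export,
coordinates relative to the same sequence):

    python examples/external_gene_comparison.py gene.fasta calls.bed

Prints per-hit calls, the analysis summary, and the strand-blind
index-set overlap between prediction and experiment.  Nothing is
downloaded by this script.
"""

import sys
from pathlib import Path

from rlfscan import (M1, M2, IntervalRecord, detect_rlfs, format_summary,
                     intervals_to_index_set, overlap_stats, read_bed,
                     read_fasta, summarize)

if len(sys.argv) != 3 or not all(Path(p).exists() for p in sys.argv[1:]):
    sys.exit("usage: external_gene_comparison.py <gene.fasta> <calls.bed>\n"
             "(both files must exist; see the module docstring)")

seq = read_fasta(sys.argv[1])[0]
experimental = read_bed(sys.argv[2])

hits = detect_rlfs(seq, (M1, M2), ("+", "-"))
print(format_summary(summarize(seq, hits)))
print()
for h in hits:
    print(f"  {h.start}-{h.end} [{h.strand}] {h.model_id} "
          f"score={h.score:.3f}")

predicted = [IntervalRecord(seq.name, h.start, h.end) for h in hits]
ref_idx = intervals_to_index_set(
    IntervalRecord(seq.name, r.start, r.end) for r in experimental)
jac, f_ref, f_pred = overlap_stats(ref_idx,
                                   intervals_to_index_set(predicted))
print(f"\noverlap with experimental calls: jaccard={jac:.1%} "
      f"experiment-covered={f_ref:.1%} prediction-covered={f_pred:.1%}")
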