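"""Chunked scanning of long sequences.

Long inputs are scanned in overlapping chunks so memory stays flat; with
the default 3 kb overlap the chunked result is identical to a single pass.
Demonstrated on a 50 kb sequence with planted motifs, including one placed
right on a chunk boundary.
"""

from rlfscan import (M1, M2, detect_chunked, detect_rlfs,
                     generate_background, plant_rlfs)

seq = generate_background(50000, 0.25, seed=21)
truth = plant_rlfs(seq, 9_950, "m1", seed=22, name="chrom")  # straddles 10 kb
residues = truth.seq.residues

whole = detect_rlfs(truth.seq, (M1, M2))

blocks = (residues[i:i + 4096] for i in range(0, len(residues), 4096))
chunked = detect_chunked(blocks, chunk_len=10000, overlap=3000,
                         models=(M1, M2), seq_name="chrom")

print(f"single pass: {len(whole)} hits; chunked: {len(chunked)} hits; "
      f"identical: {whole == chunked}")
boundary = [h for h in chunked if h.start < 10000 < h.end]
print(f"hits straddling the 10 kb chunk boundary: {len(boundary)} "
      "(each reported exactly once)")
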