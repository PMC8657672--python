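# rlfscan

Detection, scoring and validation of **R-loop forming sequences (RLFS)** in
genomic DNA.

R-loops are three-stranded nucleic acid structures — an RNA–DNA hybrid plus a
displaced single DNA strand — that form co-transcriptionally and are linked to
mutagenesis, hyper-recombination and transcription–replication conflicts.
Their formation is strongly favoured by a characteristic DNA signature:
an **R-loop initiation zone (RIZ)** of closely spaced guanine clusters, a
short **linker**, and a G-rich **R-loop elongation zone (REZ)**.  `rlfscan`
finds this signature on both strands of arbitrary-length DNA for anyone who
wants in-silico R-loop predictions: to pick candidate loci before a DRIP
experiment, to annotate a genome track, or to benchmark predictions against
experimental R-loop maps.

## Model

Two RIZ models are scanned (on the input strand, and on the reverse
complement for `-` strand hits):

* **m1** (default): ≥ 3 G-clusters of ≥ 3 guanines each,
* **m2**: ≥ 2 G-clusters of ≥ 4 guanines each,

with inter-cluster gaps of 1–10 nt and RIZ G-density ≥ 0.50.  Downstream of
each RIZ a linker of ≤ 50 nt may precede the REZ: a window of 100–2000 nt
with G-density ≥ 0.40, grown greedily in 100-nt steps and trimmed to G
boundaries.  A RIZ with no REZ is not a hit.  Every hit is scored

```
score = (g3 + 2·g4 + 3·g5) · RIZ_G% · RLOOP_G%
```

where *g3*, *g4*, *g5* count maximal G-clusters of size 3, 4 and ≥ 5 over the
whole hit, and the two densities are the G fraction of the RIZ and of the
whole hit.  All thresholds are overridable (`ModelParams` /
CLI flags such as `--max-linker`, `--rez-min-g`).

For validation, predicted and experimental interval sets are compared two
ways: nucleotide-level (intervals flattened to strand-blind index sets;
Jaccard and containment fractions) and region-level (each evaluation region
classified TP/TN/FP/FN by whether reference and/or prediction overlap it,
yielding accuracy, sensitivity, specificity, PPV/NPV and the Matthews
correlation coefficient).

## Worked example

```python
from rlfscan import M1, M2, detect_rlfs, generate_background, plant_rlfs

truth = plant_rlfs(generate_background(5000, 0.10, seed=1), 2000, "m1",
                   seed=2, name="demo")
for h in detect_rlfs(truth.seq, (M1, M2), ("+", "-")):
    print(f"{h.seq_name}:{h.start}-{h.end} [{h.strand}] model={h.model_id} "
          f"RIZ={h.riz.length}nt linker={h.linker_len}nt "
          f"REZ={h.rez.length}nt score={h.score:.4f}")
```

prints

```
demo:2000-2334 [+] model=m1 RIZ=11nt linker=23nt REZ=300nt score=0.9701
```

— one hit on the `+` strand starting exactly at the planted motif: an 11-nt
RIZ (three GGG clusters), a 23-nt linker, and a REZ the scanner extended to
300 nt because the surrounding background happens to keep the G-density
above the 0.40 floor.  The score 0.97 combines the three clusters of size 3
(`g3`-weighted) with the RIZ and whole-hit G-densities.

The same analysis from the shell, with CSV and genome-browser track export:

```sh
rlfscan generate --out-dir demo --n-seqs 1 --length 12000 --motifs 2 --seed 5
rlfscan detect demo/dataset.fasta --model both \
        --csv demo/hits.csv --bedgraph demo/track.bedgraph
```

```
sequence        synth1
length          12000 nt
R-loops found   2
R-loop rate     0.1667 per kb
covered         7.12%
CG content      51.02%
```

The CSV is 1-based inclusive with densities as percentages; the bedGraph is
0-based half-open (`seq  start  end  score`) and loads directly as a custom
genome-browser track.  Both carry `#` provenance headers recording the exact
parameter set.  `rlfscan compare --regions ... --reference ... --predicted
...` produces the validation metrics;  `rlfscan detect --chunk-len 1000000`
scans chromosome-scale input in constant memory.  See `examples/` for
narrative scripts covering each capability.

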