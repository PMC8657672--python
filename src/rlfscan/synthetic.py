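"""Synthetic sequence fixtures: random backgrounds with planted RLFS motifs.

Every planted motif is built to satisfy its detection model by construction
(and is re-validated at generation time), with ground-truth coordinates
recorded, so detection, chunking and validation can all be exercised without
any external data.

Two deliberate construction choices keep planted truth unambiguous:

* the REZ body never contains a G-run longer than 2 nt (G density is reached
  with GG dinucleotides), so a planted REZ can never seed a second,
  unintended RIZ of either model;
* the default linker (20 nt, G-free) exceeds the maximal intra-RIZ gap, so
  the RIZ cannot greedily extend into the REZ.

On a 0%-G background this makes detected hits correspond one-to-one to the
planted truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .core import find_g_clusters, g_density, reverse_complement
from .errors import ParameterError
from .models import DEFAULT_MODELS, GenomicSequence, ModelParams
from .seqio import IntervalRecord, write_fasta

_NON_G = np.array(list("ACT"))


@dataclass(frozen=True)
class PlantedTruth:
    """A sequence plus the ground-truth coordinates of its planted motifs."""

    seq: GenomicSequence
    motifs: tuple[tuple[int, int, str, str], ...]  # (start, end, strand, model)


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)


def generate_background(length: int, g_fraction: float, seed,
                        c_fraction: float | None = None) -> str:
    """I.i.d. background with P(G) = ``g_fraction``.

    By default the remaining mass is split evenly over A, C and T.  Passing
    ``c_fraction`` pins P(C) as well (the rest goes to A/T evenly); note a
    background is only G-free on *both* strands when ``g_fraction`` and
    ``c_fraction`` are both 0, since a C on the input strand is a G on the
    complementary strand.
    """
    if length < 0:
        raise ParameterError("length must be >= 0")
    if not 0.0 <= g_fraction <= 1.0:
        raise ParameterError("g_fraction must lie in [0, 1]")
    if length == 0:
        return ""
    rng = _rng(seed)
    if c_fraction is None:
        rest = (1.0 - g_fraction) / 3
        p = [g_fraction, rest, rest, rest]
    else:
        if not 0.0 <= c_fraction <= 1.0 - g_fraction:
            raise ParameterError("c_fraction must lie in [0, 1-g_fraction]")
        at = (1.0 - g_fraction - c_fraction) / 2
        p = [g_fraction, at, c_fraction, at]
    return "".join(rng.choice(list("GACT"), size=length, p=p))


def _non_g(rng: np.random.Generator, k: int) -> str:
    return "".join(rng.choice(_NON_G, size=k)) if k else ""


def _build_riz(model: ModelParams, n_tracts: int, gap_len: int,
               rng: np.random.Generator) -> str:
    parts = []
    for i in range(n_tracts):
        if i:
            parts.append(_non_g(rng, gap_len))
        parts.append("G" * model.min_tract_len)
    riz = "".join(parts)
    if not g_density(riz) >= model.min_riz_g_density:
        raise ParameterError(
            f"RIZ gaps of {gap_len} nt push G-density below "
            f"{model.min_riz_g_density}")
    return riz


def _build_rez(length: int, target_density: float,
               rng: np.random.Generator) -> str:
    """G-flush REZ of the requested density with no G-run longer than 2."""
    n_pairs = math.ceil(target_density * length / 2)
    if n_pairs < 2 or 3 * n_pairs - 1 > length:
        raise ParameterError(
            f"cannot build a {length}-nt REZ at density {target_density} "
            "with G-runs capped at 2")
    gap_budget = length - 2 * n_pairs
    k = n_pairs - 1
    base, rem = divmod(gap_budget, k)
    extra = set(rng.choice(k, size=rem, replace=False)) if rem else set()
    parts = ["GG"]
    for i in range(k):
        parts.append(_non_g(rng, base + (1 if i in extra else 0)))
        parts.append("GG")
    return "".join(parts)


def _validate_motif(motif: str, model: ModelParams, riz_len: int,
                    linker_len: int) -> None:
    """Independent re-check of a constructed motif against its model."""
    riz, rez = motif[:riz_len], motif[riz_len + linker_len:]
    tracts = find_g_clusters(riz, model.min_tract_len)
    assert len(tracts) >= model.min_tract_count
    assert tracts[0].start == 0 and tracts[-1].end == len(riz)
    assert all(b.start - a.end <= model.max_intra_riz_gap
               for a, b in zip(tracts, tracts[1:]))
    assert g_density(riz) >= model.min_riz_g_density
    assert model.min_rez_len <= len(rez) <= model.max_rez_len
    assert rez[0] == "G" and rez[-1] == "G"
    assert g_density(rez) >= model.min_rez_g_density
    assert 0 <= linker_len <= model.max_linker_len


def build_motif(model: ModelParams | str, riz_tracts: int | None = None,
                rez_len: int = 200, linker_len: int = 20,
                rez_g_density: float = 0.55, gap_len: int = 1,
                seed=0) -> str:
    """Construct one model-conformant RLFS motif (scan orientation)."""
    if isinstance(model, str):
        model = DEFAULT_MODELS[model]
    rng = _rng(seed)
    n_tracts = model.min_tract_count if riz_tracts is None else riz_tracts
    if n_tracts < model.min_tract_count:
        raise ParameterError("riz_tracts below the model's minimum count")
    if not model.min_rez_len <= rez_len <= model.max_rez_len:
        raise ParameterError("rez_len outside the model's REZ length range")
    if not 0 <= linker_len <= model.max_linker_len:
        raise ParameterError("linker_len outside [0, max_linker_len]")
    if rez_g_density < model.min_rez_g_density:
        raise ParameterError(
            f"rez_g_density {rez_g_density} below the model floor "
            f"{model.min_rez_g_density}")
    riz = _build_riz(model, n_tracts, gap_len, rng)
    motif = riz + _non_g(rng, linker_len) + _build_rez(rez_len,
                                                       rez_g_density, rng)
    _validate_motif(motif, model, len(riz), linker_len)
    return motif


def plant_rlfs(background: str, position: int, model: ModelParams | str,
               riz_tracts: int | None = None, rez_len: int = 200,
               linker_len: int = 20, seed=0, strand: str = "+",
               rez_g_density: float = 0.55, gap_len: int = 1,
               name: str = "synthetic") -> PlantedTruth:
    """Splice one RLFS motif into ``background`` at ``position``.

    On strand ``-`` the reverse complement of the motif is spliced, so the
    signature lies on the complementary strand.  Returns the new sequence
    with the ground-truth interval recorded.
    """
    if isinstance(model, str):
        model = DEFAULT_MODELS[model]
    if strand not in ("+", "-"):
        raise ParameterError("strand must be '+' or '-'")
    motif = build_motif(model, riz_tracts, rez_len, linker_len,
                        rez_g_density, gap_len, seed)
    if position < 0 or position + len(motif) > len(background):
        raise ParameterError(
            f"motif of {len(motif)} nt at {position} overflows the "
            f"{len(background)}-nt background")
    spliced = motif if strand == "+" else reverse_complement(motif)
    residues = (background[:position] + spliced
                + background[position + len(motif):])
    truth = (position, position + len(motif), strand, model.model_id)
    return PlantedTruth(GenomicSequence(name, residues), (truth,))


def generate_dataset(n_seqs: int, length: int, n_motifs_per_seq: int,
                     model_mix: Sequence[str] = ("m1", "m2"), seed=0,
                     g_fraction: float = 0.25, spacing: int = 3000,
                     rez_len: int = 200, linker_len: int = 20,
                     c_fraction: float | None = None,
                     name_prefix: str = "synth") -> list[PlantedTruth]:
    """A reproducible corpus of backgrounds with non-overlapping motifs.

    Motifs are assigned one per equal slot of the sequence with random
    offsets, keeping at least ``spacing`` nt between consecutive motifs and
    drawing strand and model (from ``model_mix``) at random.
    """
    rng = _rng(seed)
    models = [DEFAULT_MODELS[m] if isinstance(m, str) else m
              for m in model_mix]
    out: list[PlantedTruth] = []
    for s in range(n_seqs):
        residues = generate_background(length, g_fraction, rng, c_fraction)
        motifs: list[tuple[int, int, str, str]] = []
        if n_motifs_per_seq:
            slot = length // n_motifs_per_seq
            for i in range(n_motifs_per_seq):
                model = models[int(rng.integers(len(models)))]
                strand = "+" if rng.integers(2) == 0 else "-"
                motif = build_motif(model, rez_len=rez_len,
                                    linker_len=linker_len, seed=rng)
                room = slot - len(motif) - spacing
                if room < 0:
                    raise ParameterError(
                        f"{n_motifs_per_seq} motifs of {len(motif)} nt with "
                        f"{spacing} nt spacing do not fit in {length} nt")
                pos = i * slot + int(rng.integers(room + 1))
                spliced = motif if strand == "+" else \
                    reverse_complement(motif)
                residues = (residues[:pos] + spliced
                            + residues[pos + len(motif):])
                motifs.append((pos, pos + len(motif), strand,
                               model.model_id))
        out.append(PlantedTruth(
            GenomicSequence(f"{name_prefix}{s + 1}", residues),
            tuple(motifs)))
    return out


def truth_to_intervals(truths: Sequence[PlantedTruth]) -> list[IntervalRecord]:
    """Ground-truth motifs as BED-like interval records."""
    return [IntervalRecord(t.seq.name, start, end, None, strand)
            for t in truths for (start, end, strand, _model) in t.motifs]


def write_dataset(truths: Sequence[PlantedTruth], fasta_path, bed_path) -> None:
    """Emit the corpus as FASTA plus a 6-column truth BED (model as name)."""
    write_fasta((t.seq for t in truths), fasta_path)
    with open(Path(bed_path), "w", encoding="utf-8") as fh:
        for t in truths:
            for (start, end, strand, model) in t.motifs:
                fh.write(f"{t.seq.name}\t{start}\t{end}\t{model}\t0\t"
                         f"{strand}\n")
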