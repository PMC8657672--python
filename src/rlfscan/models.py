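"""Domain types for R-loop forming sequence (RLFS) detection.

An RLFS is modelled as RIZ + linker + REZ: an R-loop initiation zone made of
closely spaced guanine clusters, a short spacer, and a G-rich elongation zone
that sustains the RNA-DNA hybrid.  Two detection models are provided:

* ``m1`` — RIZ of at least three G-clusters of >= 3 guanines each,
* ``m2`` — RIZ of at least two G-clusters of >= 4 guanines each,

both with inter-cluster gaps of 1-10 nt and RIZ G-density >= 0.50, followed by
a linker of at most 50 nt and a REZ of 100-2000 nt with G-density >= 0.40.
All thresholds are overridable via :class:`ModelParams`.

Coordinate convention: every ``start``/``end`` pair in these types is 0-based
half-open and expressed in the coordinates of the input (+) strand, including
for hits detected on the complementary (-) strand.  Sequence strings, in
contrast, are always given in the 5'->3' orientation of the scanned strand
(i.e. the strand on which the G-rich signature lies).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .errors import ParameterError

VALID_MODELS = ("m1", "m2")
STRANDS = ("+", "-")

#: normalized DNA alphabet after ingest (U is mapped to T on input)
ALPHABET = frozenset("ACGTN")


@dataclass(frozen=True)
class ModelParams:
    """All thresholds of one RLFS detection model.

    Parameters
    ----------
    model_id:
        ``"m1"`` or ``"m2"``.
    min_tract_len:
        Minimum guanines per G-cluster in the RIZ.
    min_tract_count:
        Minimum number of G-clusters in the RIZ.
    max_intra_riz_gap:
        Maximum non-cluster gap (nt) between consecutive RIZ clusters.
    min_riz_g_density:
        Minimum fraction of G over the RIZ span.
    max_linker_len:
        Maximum spacer (nt) between RIZ end and REZ start.
    min_rez_len, max_rez_len:
        Allowed REZ length range (nt).
    min_rez_g_density:
        Minimum fraction of G over the REZ.
    rez_step:
        Increment (nt) of the greedy REZ window extension.
    """

    model_id: str
    min_tract_len: int
    min_tract_count: int
    max_intra_riz_gap: int = 10
    min_riz_g_density: float = 0.50
    max_linker_len: int = 50
    min_rez_len: int = 100
    max_rez_len: int = 2000
    min_rez_g_density: float = 0.40
    rez_step: int = 100

    def __post_init__(self) -> None:
        if self.model_id not in VALID_MODELS:
            raise ParameterError(f"unknown model_id {self.model_id!r}")
        if self.min_tract_len < 1 or self.min_tract_count < 1:
            raise ParameterError("cluster size and count must be >= 1")
        if self.max_intra_riz_gap < 1:
            raise ParameterError("max_intra_riz_gap must be >= 1")
        if self.max_linker_len < 0:
            raise ParameterError("max_linker_len must be >= 0")
        if not 0 < self.min_rez_len <= self.max_rez_len:
            raise ParameterError("need 0 < min_rez_len <= max_rez_len")
        if self.rez_step < 1:
            raise ParameterError("rez_step must be >= 1")
        for name in ("min_riz_g_density", "min_rez_g_density"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ParameterError(f"{name} must lie in [0, 1]")

    @property
    def min_riz_span(self) -> int:
        """Shortest RIZ this model can emit (tracts + 1-nt gaps)."""
        return (self.min_tract_len * self.min_tract_count
                + self.min_tract_count - 1)

    @property
    def max_reach(self) -> int:
        """Longest stretch scanned downstream of a RIZ end."""
        return self.max_linker_len + self.max_rez_len


#: default model m1: three clusters of >= 3 Gs
M1 = ModelParams("m1", min_tract_len=3, min_tract_count=3)
#: alternative model m2: two clusters of >= 4 Gs
M2 = ModelParams("m2", min_tract_len=4, min_tract_count=2)

DEFAULT_MODELS = {"m1": M1, "m2": M2}


def model_params(model_id: str, **overrides) -> ModelParams:
    """Return the default parameter set of a model, with overrides applied."""
    try:
        base = DEFAULT_MODELS[model_id]
    except KeyError:
        raise ParameterError(f"unknown model_id {model_id!r}") from None
    return replace(base, **overrides) if overrides else base


@dataclass(frozen=True)
class GenomicSequence:
    """A named DNA sequence over {A,C,G,T,N}, the unit of analysis."""

    name: str
    residues: str
    description: str = ""

    @property
    def length(self) -> int:
        return len(self.residues)

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class GCluster:
    """A maximal run of consecutive guanines, 0-based half-open."""

    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class RIZ:
    """R-loop initiation zone: consecutive qualifying G-clusters.

    ``start``/``end`` are input(+) coordinates; ``sequence`` is in scan
    orientation and both begins and ends with G.
    """

    start: int
    end: int
    sequence: str
    g_density: float
    tracts: tuple[GCluster, ...]
    model_id: str

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class REZ:
    """R-loop elongation zone; G-flush at both ends, scan orientation."""

    start: int
    end: int
    sequence: str
    g_density: float

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class ScoreComponents:
    """Cluster counts and densities entering the RLFS score.

    ``g3``/``g4``/``g5`` count maximal G-clusters of length exactly 3,
    exactly 4 and >= 5 over the whole RLFS span; ``riz_g`` is the RIZ
    G-density and ``rloop_g`` the G-density of the whole span (fractions).
    """

    g3: int
    g4: int
    g5: int
    riz_g: float
    rloop_g: float


@dataclass(frozen=True)
class RLFSHit:
    """One detected R-loop forming sequence.

    ``score = (g3 + 2*g4 + 3*g5) * riz_g * rloop_g``.
    """

    seq_name: str
    strand: str
    model_id: str
    start: int
    end: int
    riz: RIZ
    linker_len: int
    rez: REZ
    components: ScoreComponents
    score: float

    @property
    def length(self) -> int:
        return self.end - self.start

    def key(self) -> tuple:
        """Identity used for deduplication and ordering."""
        return (self.start, self.end, self.strand, self.model_id)
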