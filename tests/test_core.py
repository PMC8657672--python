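"""Unit tests for the detection primitives and the strand/chunk plumbing."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rlfscan import (
    GenomicSequence,
    M1,
    M2,
    ParameterError,
    ScoreComponents,
    compute_score,
    detect_chunked,
    detect_rlfs,
    find_g_clusters,
    find_rez,
    find_riz,
    g_density,
    map_to_plus,
    model_params,
    reverse_complement,
)
from conftest import as_sequence

dna = st.text(alphabet="ACGTN", min_size=0, max_size=200)


@pytest.mark.parametrize("residues,min_len,expected", [
    ("GGG", 3, [(0, 3)]),
    ("ACGTACGT", 3, []),
    ("GGGGAGGGTGG", 3, [(0, 4), (5, 8)]),
    ("GNGGG", 1, [(0, 1), (2, 5)]),  # N never counts as G
])
def test_find_g_clusters_maximal_runs(residues, min_len, expected):
    got = [(c.start, c.end) for c in find_g_clusters(residues, min_len)]
    assert got == expected


def test_find_g_clusters_rejects_min_len_zero():
    with pytest.raises(ParameterError):
        find_g_clusters("GGG", 0)


@pytest.mark.parametrize("residues,expected", [
    ("GGGG", 1.0),
    ("GAGA", 0.5),
    ("GGNN", 0.5),  # N counts in the denominator only
])
def test_g_density(residues, expected):
    assert g_density(residues) == expected


def test_g_density_empty_is_an_error():
    with pytest.raises(ParameterError):
        g_density("")


class TestFindRiz:
    def test_three_cluster_riz_spans_all_tracts(self):
        rizs = find_riz("GGGAGGGAGGG", M1)
        assert len(rizs) == 1
        riz = rizs[0]
        assert (riz.start, riz.end) == (0, 11)
        assert len(riz.tracts) == 3
        assert riz.g_density == pytest.approx(9 / 11)

    def test_two_clusters_fail_model_m1(self):
        assert find_riz("GGGAGGG", M1) == []

    def test_model_m2_accepts_two_four_g_clusters(self):
        rizs = find_riz("GGGGAGGGG", M2)
        assert len(rizs) == 1
        assert (rizs[0].start, rizs[0].end) == (0, 9)
        assert len(rizs[0].tracts) == 2

    def test_gap_above_limit_breaks_the_chain(self):
        seq = "GGG" + "A" * 11 + "GGGAGGGAGGG"
        rizs = find_riz(seq, M1)
        assert [(r.start, r.end) for r in rizs] == [(14, 25)]

    def test_riz_is_g_flush(self, small_corpus):
        for residues in small_corpus[:50]:
            for riz in find_riz(residues, M1):
                assert residues[riz.start] == "G"
                assert residues[riz.end - 1] == "G"


class TestFindRez:
    def test_no_g_downstream_returns_none(self):
        assert find_rez("AT" * 300, 0, M1) is None

    def test_planted_g_rich_window_is_found(self):
        residues = "AT" * 5 + "GGAT" * 50 + "AT" * 100
        found = find_rez(residues, 0, M1)
        assert found is not None
        linker, rez = found
        assert linker == 10
        assert rez.length >= M1.min_rez_len
        assert rez.sequence[0] == "G" and rez.sequence[-1] == "G"

    def test_g_region_beyond_max_linker_is_ignored(self):
        residues = "A" * (M1.max_linker_len + 1) + "GGAT" * 100
        assert find_rez(residues, 0, M1) is None

    def test_out_of_range_search_from(self):
        with pytest.raises(ParameterError):
            find_rez("ACGT", 10, M1)


@pytest.mark.parametrize("comps,expected", [
    (ScoreComponents(1, 0, 0, 0.5, 0.5), 0.25),
    (ScoreComponents(0, 0, 0, 0.9, 0.9), 0.0),
    (ScoreComponents(2, 1, 1, 0.6, 0.5), pytest.approx(2.1)),
])
def test_compute_score_formula(comps, expected):
    assert compute_score(comps) == expected


@pytest.mark.parametrize("residues,expected", [
    ("ACGT", "ACGT"),
    ("GGG", "CCC"),
    ("ACGTN", "NACGT"),
])
def test_reverse_complement(residues, expected):
    assert reverse_complement(residues) == expected


def test_reverse_complement_rejects_bad_alphabet():
    with pytest.raises(Exception):
        reverse_complement("ACGX")


@settings(derandomize=True, max_examples=50)
@given(dna)
def test_reverse_complement_involution(residues):
    assert reverse_complement(reverse_complement(residues)) == residues


@pytest.mark.parametrize("start,end,n,expected", [
    (0, 3, 10, (7, 10)),
    (0, 10, 10, (0, 10)),
    (2, 5, 12, (7, 10)),
])
def test_map_to_plus(start, end, n, expected):
    assert map_to_plus(start, end, n) == expected


def test_map_to_plus_rejects_out_of_range():
    with pytest.raises(ParameterError):
        map_to_plus(5, 12, 10)


class TestDetect:
    def test_empty_and_all_n_sequences_yield_nothing(self):
        assert detect_rlfs(as_sequence(""), (M1, M2)) == []
        assert detect_rlfs(as_sequence("N" * 500), (M1, M2)) == []

    def test_planted_motif_recovered_on_plus(self, planted_m1):
        start, end, strand, model = planted_m1.motifs[0]
        hits = detect_rlfs(planted_m1.seq, (M1,), ("+",))
        assert any(h.start < end and h.end > start and h.strand == "+"
                   and h.model_id == "m1" for h in hits)

    def test_needs_model_and_strand(self, planted_m1):
        with pytest.raises(ParameterError):
            detect_rlfs(planted_m1.seq, ())
        with pytest.raises(ParameterError):
            detect_rlfs(planted_m1.seq, (M1,), strands=())

    def test_hits_sorted_and_length_consistent(self, small_corpus):
        for residues in small_corpus[:50]:
            hits = detect_rlfs(as_sequence(residues), (M1, M2))
            assert hits == sorted(hits, key=lambda h: h.key())
            for h in hits:
                assert h.length == h.riz.length + h.linker_len + h.rez.length

    def test_every_hit_revalidates_against_its_model(self, small_corpus):
        """Hit substrings independently satisfy all model constraints."""
        models = {"m1": M1, "m2": M2}
        for residues in small_corpus[:60]:
            n = len(residues)
            for h in detect_rlfs(as_sequence(residues), (M1, M2)):
                p = models[h.model_id]
                if h.strand == "+":
                    riz_seq = residues[h.riz.start:h.riz.end]
                    rez_seq = residues[h.rez.start:h.rez.end]
                else:
                    riz_seq = reverse_complement(
                        residues[h.riz.start:h.riz.end])
                    rez_seq = reverse_complement(
                        residues[h.rez.start:h.rez.end])
                assert riz_seq == h.riz.sequence
                assert rez_seq == h.rez.sequence
                tracts = find_g_clusters(riz_seq, p.min_tract_len)
                assert len(tracts) >= p.min_tract_count
                assert tracts[0].start == 0
                assert tracts[-1].end == len(riz_seq)
                assert all(b.start - a.end <= p.max_intra_riz_gap
                           for a, b in zip(tracts, tracts[1:]))
                assert g_density(riz_seq) >= p.min_riz_g_density - 1e-9
                assert p.min_rez_len <= len(rez_seq) <= p.max_rez_len
                assert g_density(rez_seq) >= p.min_rez_g_density - 1e-9
                assert 0 <= h.linker_len <= p.max_linker_len
                comps = h.components
                assert h.score == pytest.approx(
                    (comps.g3 + 2 * comps.g4 + 3 * comps.g5)
                    * comps.riz_g * comps.rloop_g)


class TestDetectChunked:
    def test_sequence_shorter_than_chunk(self, planted_m1):
        whole = detect_rlfs(planted_m1.seq, (M1,))
        chunked = detect_chunked([planted_m1.seq.residues], 10000, 3000,
                                 (M1,), seq_name=planted_m1.seq.name)
        assert chunked == whole

    def test_overlap_too_small_is_rejected(self):
        with pytest.raises(ParameterError):
            detect_chunked(["ACGT"], 4000, 100, (M1,))

    def test_chunk_len_must_exceed_overlap(self):
        with pytest.raises(ParameterError):
            detect_chunked(["ACGT"], 3000, 3000, (M1,))


def test_model_params_overrides_and_validation():
    m = model_params("m1", max_linker_len=10)
    assert m.max_linker_len == 10 and m.min_tract_count == 3
    with pytest.raises(ParameterError):
        model_params("m3")
    with pytest.raises(ParameterError):
        model_params("m1", min_rez_len=0)
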