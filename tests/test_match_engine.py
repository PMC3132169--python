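"""Built-in aligner, tabular hit I/O, window rule and self-matching."""

from __future__ import annotations

import io

import numpy as np
import pytest

from oakbes._util import revcomp
from oakbes.match_engine import (
    AlignmentHit,
    AlignParams,
    TabularParseError,
    local_align,
    read_tabular_hits,
    self_match_counts,
    window_identity_pass,
    write_tabular_hits,
)
from tests._oracles import sw_best_score
from tests.conftest import mutate, random_seq


def _hit(match_vector, **kw):
    defaults = dict(
        query_id="q", subject_id="s", q_start=1, q_end=len(match_vector),
        s_start=1, s_end=len(match_vector), subject_strand="+",
        match_vector=np.asarray(match_vector, dtype=bool),
    )
    defaults.update(kw)
    return AlignmentHit(**defaults)


class TestWindowRule:
    def test_perfect_100mer_passes(self):
        assert window_identity_pass(_hit([True] * 100))

    def test_threshold_is_90_matches_inclusive(self):
        ten_off = [False] * 10 + [True] * 90
        eleven_off = [False] * 11 + [True] * 89
        assert window_identity_pass(_hit(ten_off))
        assert not window_identity_pass(_hit(eleven_off))

    def test_clustered_mismatches_fail_one_window(self):
        # 200 columns, 15 mismatches inside columns 50-149: that window has 85 matches
        mv = np.ones(200, dtype=bool)
        mv[50:65] = False
        assert not window_identity_pass(_hit(mv))
        # the same 15 mismatches spread evenly pass every window
        mv2 = np.ones(200, dtype=bool)
        mv2[::14][:15] = False
        assert window_identity_pass(_hit(mv2))

    def test_short_alignment_never_passes(self):
        assert not window_identity_pass(_hit([True] * 99))

    def test_requires_match_vector_and_positive_window(self):
        with pytest.raises(ValueError):
            window_identity_pass(_hit([True] * 100), w=0)
        bare = _hit([True] * 100)
        bare.match_vector = None
        with pytest.raises(ValueError):
            window_identity_pass(bare)


class TestLocalAlign:
    def test_identical_sequences_single_perfect_hit(self, rng):
        s = random_seq(rng, 120)
        hits = local_align(s, s)
        assert hits[0].identity == 1.0
        assert hits[0].n_columns == 120
        assert hits[0].subject_strand == "+"

    def test_reverse_complement_found_on_minus_strand(self, rng):
        s = random_seq(rng, 120)
        hits = local_align(s, revcomp(s))
        best = hits[0]
        assert best.subject_strand == "-"
        assert (best.s_start, best.s_end) == (1, 120)
        assert best.identity == 1.0

    def test_empty_sequence_is_an_error(self):
        with pytest.raises(ValueError):
            local_align("", "ACGT")

    def test_scattered_substitutions_match_dp_oracle(self, rng):
        a = random_seq(rng, 200)
        b = list(a)
        for i in rng.choice(200, size=12, replace=False):
            b[i] = [c for c in "ACGT" if c != b[i]][int(rng.integers(3))]
        b = "".join(b)
        hits = local_align(a, b)
        assert hits[0].score == pytest.approx(sw_best_score(a, b))

    def test_no_hit_below_min_score(self, rng):
        a = random_seq(rng, 40)
        b = revcomp(a)  # only a minus-strand hit exists
        hits = local_align(a, b, AlignParams(min_score=1_000))
        assert hits == []

    def test_oracle_equivalence_on_random_related_pairs(self, rng):
        """Seed-and-extend best score equals the full Smith-Waterman DP.

        Pairs are mutated copies (5% divergence) of lengths 60-500 plus
        unrelated pairs.  When the word-size gate suppresses alignment
        entirely, the pair must either lack a shared 11-mer or fall
        below the score floor.
        """
        from oakbes.match_engine import _kmers

        params = AlignParams()
        n_checked = 0
        for trial in range(220):
            n = int(rng.integers(60, 501))
            a = random_seq(rng, n)
            if trial % 3 == 2:
                b = random_seq(rng, n)  # unrelated
            else:
                b = mutate(rng, a, 0.05)
                if trial % 2:
                    b = revcomp(b)
            hits = local_align(a, b, params)
            oracle = sw_best_score(a, b)
            if hits:
                assert hits[0].score == pytest.approx(oracle)
                n_checked += 1
            else:
                shared = bool(_kmers(a, 11) & _kmers(b, 11)) or bool(
                    _kmers(a, 11) & _kmers(revcomp(b), 11)
                )
                assert (not shared) or oracle < params.min_score
        assert n_checked >= 100  # the equality branch must be exercised


class TestTabularIO:
    FIXTURE = (
        "readA\tchr1\t98.00\t100\t2\t0\t1\t100\t5001\t5100\t1e-40\t180\n"
        "readB\tchr1\t95.50\t200\t9\t1\t3\t200\t9000\t8801\t1e-60\t250\n"
        "readC\tchr2\t100.00\t150\t0\t0\t1\t150\t1\t150\t0.0\t300\n"
    )

    def test_fixture_fields_round_trip(self):
        hits = read_tabular_hits(io.StringIO(self.FIXTURE))
        assert len(hits) == 3
        a, b, c = hits
        assert (a.query_id, a.subject_id, a.evalue) == ("readA", "chr1", 1e-40)
        assert (a.q_start, a.q_end, a.s_start, a.s_end, a.subject_strand) == (
            1, 100, 5001, 5100, "+",
        )
        assert (c.s_start, c.s_end) == (1, 150)

    def test_reversed_subject_coordinates_canonicalized(self):
        hits = read_tabular_hits(io.StringIO(self.FIXTURE))
        b = hits[1]
        assert b.subject_strand == "-"
        assert (b.s_start, b.s_end) == (8_801, 9_000)

    def test_empty_stream(self):
        assert read_tabular_hits(io.StringIO("")) == []

    def test_column_count_error_names_line(self):
        with pytest.raises(TabularParseError, match="line 2"):
            read_tabular_hits(io.StringIO("a\tb\t100\t5\t0\t0\t1\t5\t1\t5\t0\t10\nbad\tline\n"))

    def test_approximate_match_vector_spreads_mismatches(self):
        hits = read_tabular_hits(io.StringIO(self.FIXTURE), approximate=True)
        a = hits[0]
        assert a.n_columns == 100
        assert int(a.match_vector.sum()) == 98
        assert window_identity_pass(a)

    def test_write_then_read_round_trip(self, rng):
        s = random_seq(rng, 150)
        hits = local_align(s, s, query_id="x", subject_id="y")
        buf = io.StringIO()
        write_tabular_hits(hits, buf)
        buf.seek(0)
        again = read_tabular_hits(buf, approximate=True)
        assert len(again) == 1
        h = again[0]
        assert (h.query_id, h.subject_id) == ("x", "y")
        assert (h.q_start, h.q_end, h.s_start, h.s_end) == (1, 150, 1, 150)
        assert h.identity == 1.0


class TestSelfMatch:
    def test_shared_element_forms_complete_graph(self, reads_with_element):
        reads, _ = reads_with_element(5, read_len=400, elem_len=150)
        counts = self_match_counts(reads)
        assert all(counts[r.read_id] == 4 for r in reads)

    def test_random_reads_do_not_match(self, background_reads):
        reads = background_reads(30, read_len=600)
        counts = self_match_counts(reads)
        assert counts.total_matching == 0

    def test_counts_are_symmetric_under_role_swap(self, reads_with_element, rng):
        reads, _ = reads_with_element(4, read_len=300, elem_len=120)
        forward = self_match_counts(reads)
        backward = self_match_counts(list(reversed(reads)))
        assert forward.counts == backward.counts

    def test_masking_can_only_decrease_counts(self, reads_with_element):
        reads, element = reads_with_element(6, read_len=400, elem_len=150)
        unmasked = self_match_counts(reads)
        # mask the planted element in half the reads
        mask = {}
        for r in reads[:3]:
            pos = r.sequence.find(element)
            mask[r.read_id] = [(pos + 1, pos + len(element))]
        masked = self_match_counts(reads, mask=mask)
        assert all(masked[rid] <= unmasked[rid] for rid in masked.counts)
        assert masked.total_matching < unmasked.total_matching

    def test_divergent_element_still_detected(self, reads_with_element):
        reads, _ = reads_with_element(5, read_len=400, elem_len=200, divergence=0.02)
        counts = self_match_counts(reads)
        assert all(counts[r.read_id] >= 3 for r in reads)
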