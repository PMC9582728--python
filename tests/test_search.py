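"""Translation, local alignment, E-value statistics, and search."""

import math
import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kscan import (
    BlastpAdapter,
    QueryRecord,
    SearchParams,
    detect_alphabet,
    evalue_from_score,
    search_all,
    six_frame_translate,
    smith_waterman,
    sw_score,
)
from kscan.errors import DataError, EngineError
from kscan.refdb import ReferenceDB, Taxonomy

from .oracles import brute_force_local_score

AA = "ACDEFGHIKLMNPQRSTVWY"
NT = "ACGT"


def revcomp(s):
    return s.translate(str.maketrans("ACGT", "TGCA"))[::-1]


class TestAlphabet:
    @pytest.mark.parametrize(
        "seq,expected",
        [
            ("ACGTACGT", "nucleotide"),
            ("MKVLAWHE", "protein"),
            ("ACGTMKVL", "protein"),  # 50% ACGT, below the 90% rule
            ("acgtacgtnn", "nucleotide"),
        ],
    )
    def test_detection(self, seq, expected):
        assert detect_alphabet(seq) == expected

    def test_empty_is_error(self):
        with pytest.raises(DataError):
            detect_alphabet("")


class TestSixFrame:
    def test_standard_code_with_stop(self):
        frames = {f.frame: f.peptide for f in
                  six_frame_translate(QueryRecord("q", "ATGGCCTAA"))}
        assert frames[1] == "MA*"

    def test_trailing_bases_ignored(self):
        frames = {f.frame: f.peptide for f in
                  six_frame_translate(QueryRecord("q", "ATGGCCTA"))}
        assert len(frames[1]) == 2  # floor(8/3)
        assert len(frames[2]) == 2
        assert len(frames[3]) == 2

    def test_ambiguity_codes_become_x(self):
        frames = {f.frame: f.peptide for f in
                  six_frame_translate(QueryRecord("q", "ATGNNNTAA"))}
        assert frames[1] == "MX*"

    def test_reverse_frames_equal_forward_frames_of_revcomp(self):
        rng = random.Random(42)
        for _ in range(20):
            seq = "".join(rng.choice(NT) for _ in range(rng.randrange(30, 90)))
            fwd = {f.frame: f.peptide for f in
                   six_frame_translate(QueryRecord("q", seq))}
            rev = {f.frame: f.peptide for f in
                   six_frame_translate(QueryRecord("q", revcomp(seq)))}
            for k in (1, 2, 3):
                assert fwd[-k] == rev[k]

    def test_nt_span_back_mapping_is_exact(self):
        rng = random.Random(1)
        seq = "".join(rng.choice(NT) for _ in range(60))
        for trans in six_frame_translate(QueryRecord("q", seq)):
            for i in range(1, len(trans.peptide) + 1):
                start, end, strand = trans.nt_span(i, i)
                assert end - start == 2  # one codon
                codon = seq[start - 1 : end]
                if strand == "-":
                    codon = revcomp(codon)
                from Bio.Seq import Seq

                assert str(Seq(codon).translate()) == trans.peptide[i - 1]


class TestSmithWaterman:
    def test_ungapped_self_alignment_score(self):
        # sum of BLOSUM62 diagonal entries for ARNDCQ (brute-force verified)
        assert brute_force_local_score("ARNDCQ", "ARNDCQ") == 35
        aln = smith_waterman("ARNDCQ", "ARNDCQ")
        assert aln.score == 35 and aln.percent_identity == 100.0

    def test_no_positive_pair_scores_empty(self):
        aln = smith_waterman("AAAA", "CCCC")
        assert aln.score == 0 and aln.length == 0

    def test_short_local_alignment_matches_oracle(self):
        expected = brute_force_local_score("MKVLA", "MKLA")
        aln = smith_waterman("MKVLA", "MKLA")
        assert aln.score == expected

    def test_alignment_never_crosses_stop(self):
        left, right = "MKVLAWHE", "GDRTYFQN"
        target = left + right
        aln = smith_waterman(left + "*" + right, target)
        # best local alignment confined to one side of the stop
        assert "*" not in aln.aligned_query
        assert aln.score == max(
            smith_waterman(left, target).score,
            smith_waterman(right, target).score,
        )

    @given(
        st.text(alphabet=AA, min_size=1, max_size=30),
        st.text(alphabet=AA, min_size=1, max_size=30),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_matches_brute_force_oracle(self, q, t):
        assert sw_score(q, t) == brute_force_local_score(q, t)

    def test_full_and_score_only_agree(self):
        rng = random.Random(3)
        for _ in range(50):
            q = "".join(rng.choice(AA) for _ in range(rng.randrange(5, 60)))
            t = "".join(rng.choice(AA) for _ in range(rng.randrange(5, 60)))
            assert smith_waterman(q, t).score == sw_score(q, t)

    def test_realigning_reported_spans_reproduces_score(self):
        rng = random.Random(4)
        for _ in range(20):
            q = "".join(rng.choice(AA) for _ in range(40))
            t = "".join(rng.choice(AA) for _ in range(40))
            aln = smith_waterman(q, t)
            if aln.score == 0:
                continue
            sub_q = q[aln.query_start - 1 : aln.query_end]
            sub_t = t[aln.target_start - 1 : aln.target_end]
            assert smith_waterman(sub_q, sub_t).score == aln.score


class TestEvalue:
    def test_closed_form(self):
        p = SearchParams()
        bit, ev = evalue_from_score(100, 200, 100_000, p)
        expected_bit = (0.267 * 100 - math.log(0.041)) / math.log(2)
        assert bit == pytest.approx(expected_bit)
        assert ev == pytest.approx(200 * 100_000 * 2 ** (-expected_bit))

    def test_monotone_in_score(self):
        evs = [evalue_from_score(s, 200, 1000)[1] for s in range(10, 100, 10)]
        assert all(a > b for a, b in zip(evs, evs[1:]))

    def test_linear_in_db_length(self):
        _, e1 = evalue_from_score(50, 200, 1000)
        _, e2 = evalue_from_score(50, 200, 2000)
        assert e2 == pytest.approx(2 * e1)


class TestSearchAll:
    def test_identical_query_is_top_hit(self, small_db):
        db, _ = small_db
        dom = db.domains[0]
        hits = search_all([QueryRecord("q", dom.sequence, "protein")], db)
        assert hits[0].db_id == dom.id
        assert hits[0].percent_identity == 100.0

    def test_revcomp_embedding_same_hit_negative_frame(self, small_db):
        import numpy as np

        from kscan.simulate import reverse_translate

        db, _ = small_db
        dom = db.domains[1]
        rng = np.random.default_rng(5)
        nt = reverse_translate(dom.sequence, rng)
        fwd_hits = search_all([QueryRecord("q", nt, "nucleotide")], db)
        rev_hits = search_all([QueryRecord("q", revcomp(nt), "nucleotide")], db)
        top_f, top_r = fwd_hits[0], rev_hits[0]
        assert top_f.db_id == top_r.db_id == dom.id
        assert top_f.frame == 1 and top_r.frame == -1
        assert (top_f.query_start, top_f.query_end) == (
            top_r.query_start, top_r.query_end,
        )
        assert top_r.strand == "-"

    def test_evalue_order_equals_bitscore_order(self, small_db):
        db, _ = small_db
        hits = search_all([QueryRecord("q", db.domains[2].sequence, "protein")], db)
        by_ev = [h.db_id for h in sorted(hits, key=lambda h: h.evalue)]
        by_bit = [h.db_id for h in sorted(hits, key=lambda h: -h.bit_score)]
        assert by_ev == by_bit

    def test_builtin_refuses_oversized_database(self, small_db):
        db, _ = small_db
        params = SearchParams(max_builtin_db_size=2)
        with pytest.raises(EngineError, match="external"):
            search_all([QueryRecord("q", "MKVLAWHE", "protein")], db, params)

    def test_blastp_adapter_agrees_on_top_hit(self, small_db):
        db, _ = small_db
        dom = db.domains[5]
        query = [QueryRecord("q", dom.sequence, "protein")]
        builtin = search_all(query, db)
        external = search_all(query, db, engine=BlastpAdapter())
        assert external[0].db_id == builtin[0].db_id == dom.id
        assert external[0].percent_identity == pytest.approx(100.0)
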