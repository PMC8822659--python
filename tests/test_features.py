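"""Alignment backend and normalized-bit-score feature encoding."""

import dataclasses

import numpy as np
import pytest

from tfscout.database import merge_and_curate, TFRecord
from tfscout.errors import ConsistencyError, NumericError, ParameterError
from tfscout.features import (
    AlignerParams,
    AlignmentHit,
    align_all,
    build_feature_matrix,
    make_aligner,
    normalized_bitscore,
    read_hits_tsv,
    self_bit_score,
    write_hits_tsv,
)
from tfscout.simulate import generate_family_set, FamilySpec

from helpers import gotoh_local_score

AA = list("ACDEFGHIKLMNPQRSTVWY")


def queries_of(db):
    return [(r.record_id, r.sequence) for r in db.records]


class TestAlignAll:
    def test_self_match_is_full_identity(self, small_db, aligner_params):
        rec = small_db.records[0]
        hits = align_all([("probe", rec.sequence)], small_db, aligner_params)
        self_hits = [h for h in hits if h.subject_id == rec.record_id]
        assert self_hits and self_hits[0].identity_pct == 100.0

    def test_hits_respect_thresholds(self, small_db, aligner_params):
        hits = align_all(queries_of(small_db), small_db, aligner_params)
        assert hits
        for h in hits:
            assert h.identity_pct >= aligner_params.min_identity_pct
            assert h.evalue <= aligner_params.max_evalue
            assert h.bit_score > 0

    def test_threshold_tightening_is_monotone(self, small_db, aligner_params):
        base = {(h.query_id, h.subject_id)
                for h in align_all(queries_of(small_db), small_db, aligner_params)}
        tighter = dataclasses.replace(aligner_params, max_evalue=1e-40, min_identity_pct=50.0)
        subset = {(h.query_id, h.subject_id)
                  for h in align_all(queries_of(small_db), small_db, tighter)}
        assert subset <= base

    def test_max_hits_truncates_deterministically(self, small_db, aligner_params):
        capped = dataclasses.replace(aligner_params, max_hits=2)
        hits = align_all(queries_of(small_db)[:3], small_db, capped)
        per_query = {}
        for h in hits:
            per_query.setdefault(h.query_id, []).append(h)
        for hs in per_query.values():
            assert len(hs) <= 2
            bits = [h.bit_score for h in hs]
            assert bits == sorted(bits, reverse=True)

    def test_empty_inputs_rejected(self, small_db, aligner_params):
        with pytest.raises(ParameterError):
            align_all([], small_db, aligner_params)
        empty = merge_and_curate([[TFRecord("x", "MKV", family="LysR")]])
        empty.records = []
        with pytest.raises(ParameterError):
            align_all([("q", "MKV")], empty, aligner_params)


class TestOracleEquivalence:
    def test_builtin_scores_equal_dp_oracle(self, aligner_params):
        """Raw Smith-Waterman scores match an explicit Gotoh DP on short pairs."""
        rng = np.random.default_rng(123)
        aligner = make_aligner(aligner_params)
        for _ in range(10):
            a = "".join(rng.choice(AA, size=int(rng.integers(10, 61))))
            b = "".join(rng.choice(AA, size=int(rng.integers(10, 61))))
            assert aligner.score(a, b) == gotoh_local_score(a, b)

    def test_related_pair_scores_match_oracle(self, small_records, aligner_params):
        aligner = make_aligner(aligner_params)
        a = small_records[0].sequence[:60]
        b = small_records[1].sequence[:60]
        assert aligner.score(a, b) == gotoh_local_score(a, b)


class TestNormalizedBitscore:
    def test_self_hit_is_one(self, small_db, aligner_params):
        rec = small_db.records[0]
        self_bits = self_bit_score(rec.sequence, aligner_params)
        hit = AlignmentHit("q", rec.record_id, bit_score=self_bits,
                           identity_pct=100.0, evalue=0.0)
        assert normalized_bitscore(hit, self_bits) == 1.0

    def test_related_pair_strictly_between_zero_and_one(self, small_records, aligner_params):
        a, b = small_records[0], small_records[1]  # same family, mutated copies
        db = merge_and_curate([[b]])
        hits = align_all([(a.record_id, a.sequence)], db, aligner_params)
        assert hits
        value = normalized_bitscore(hits[0], self_bit_score(a.sequence, aligner_params))
        assert 0.0 < value < 1.0

    def test_nonpositive_self_score_rejected(self):
        hit = AlignmentHit("q", "s", bit_score=10.0, identity_pct=50.0, evalue=1e-20)
        with pytest.raises(NumericError):
            normalized_bitscore(hit, 0.0)


class TestFeatureMatrix:
    def test_self_column_is_one_everywhere(self, small_db, aligner_params):
        queries = queries_of(small_db)
        hits = align_all(queries, small_db, aligner_params)
        fm = build_feature_matrix(queries, small_db, hits, aligner_params)
        values = fm.values.to_numpy()
        assert np.all((values >= 0.0) & (values <= 1.0))
        assert np.allclose(np.diag(values), 1.0)

    def test_no_hit_row_is_zero_and_flagged(self, small_db, aligner_params):
        queries = [("stranger", "".join(["W", "P"] * 40))]
        hits = align_all(queries, small_db, aligner_params)
        fm = build_feature_matrix(queries, small_db, hits, aligner_params)
        assert fm.no_hit == ["stranger"]
        assert np.all(fm.values.to_numpy() == 0.0)

    def test_row_permutation_only_permutes_rows(self, small_db, aligner_params):
        queries = queries_of(small_db)[:4]
        hits = align_all(queries, small_db, aligner_params)
        fm1 = build_feature_matrix(queries, small_db, hits, aligner_params)
        rev = list(reversed(queries))
        hits2 = align_all(rev, small_db, aligner_params)
        fm2 = build_feature_matrix(rev, small_db, hits2, aligner_params)
        assert fm1.values.sort_index().equals(fm2.values.sort_index())

    def test_unknown_subject_raises(self, small_db, aligner_params):
        bad = [AlignmentHit("q0", "ghost", 50.0, 90.0, 1e-30)]
        with pytest.raises(ConsistencyError):
            build_feature_matrix([("q0", "MKV" * 10)], small_db, bad, aligner_params)


class TestHitsTabular:
    def test_roundtrip(self, tmp_path, small_db, aligner_params):
        queries = queries_of(small_db)[:3]
        hits = align_all(queries, small_db, aligner_params)
        path = tmp_path / "hits.tsv"
        write_hits_tsv(hits, path)
        loaded = read_hits_tsv(path)
        assert len(loaded) == len(hits)
        for orig, back in zip(hits, loaded):
            assert (orig.query_id, orig.subject_id) == (back.query_id, back.subject_id)
            assert back.bit_score == pytest.approx(orig.bit_score, abs=0.05)
            assert back.q_start == orig.q_start and back.s_end == orig.s_end


class TestBlastBackend:
    def test_blast_contract_matches_builtin_hit_set(self, aligner_params):
        """The external blastp backend honours the same threshold contract."""
        records = generate_family_set(
            [FamilySpec("FamA", 4, 120, 0.03), FamilySpec("FamB", 4, 120, 0.03)], seed=2
        )
        db = merge_and_curate([records])
        params = dataclasses.replace(aligner_params, backend="blast")
        queries = [(r.record_id, r.sequence) for r in db.records[:3]]
        hits = align_all(queries, db, params)
        assert hits
        for h in hits:
            assert h.identity_pct >= params.min_identity_pct
            assert h.evalue <= params.max_evalue
        # each query finds itself with full identity
        for qid, _ in queries:
            own = [h for h in hits if h.query_id == qid and h.subject_id == qid]
            assert own and own[0].identity_pct == 100.0
        fm = build_feature_matrix(queries, db, hits, params)
        values = fm.values.to_numpy()
        assert np.all((values >= 0.0) & (values <= 1.0))
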