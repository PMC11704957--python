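"""Hit parsing and filtering, pairwise identity, redundancy removal, ranking."""

import numpy as np
import pytest

from enzrank.embedders import SurrogateEmbedder, embed_dataset
from enzrank.homology import (
    HomologyHit,
    filter_hits,
    identity_vs_prediction,
    pairwise_identity,
    parse_hits_m8,
    rank_candidates,
    redundancy_filter,
    write_hits_m8,
)
from enzrank.regression import RegressorSpec, grid_search_train
from enzrank.seqio import SequenceRecord
from enzrank.synthfit import generate_landscape, generate_toy_hits

_AA = list("ACDEFGHIKLMNPQRSTVWY")


def _hit(**kw):
    base = dict(
        query_id="q", target_id="t", percent_identity=50.0, aln_len=100,
        mismatches=50, gap_openings=0, q_start=1, q_end=100, t_start=1,
        t_end=100, evalue=1e-10, bit_score=200.0, q_len=100, t_len=100,
    )
    base.update(kw)
    return HomologyHit(**base)


class TestParseM8:
    def test_toy_file(self, tmp_path):
        content, _ = generate_toy_hits(seed=0, n=3, frac_fail_evalue=0, frac_fail_cov=0)
        p = tmp_path / "h.m8"
        p.write_text(content)
        assert len(parse_hits_m8(p)) == 3

    def test_wrong_column_count_reports_line(self, tmp_path):
        p = tmp_path / "h.m8"
        p.write_text("a\tb\t1\t2\t3\t4\t5\t6\t7\t8\t9\n")  # 11 columns
        with pytest.raises(ValueError, match=":1"):
            parse_hits_m8(p)

    def test_unparseable_number_reports_line(self, tmp_path):
        good, _ = generate_toy_hits(seed=0, n=1, frac_fail_evalue=0, frac_fail_cov=0)
        bad = good.replace("query\t", "query\t", 1).split("\t")
        bad[2] = "xx"
        p = tmp_path / "h.m8"
        p.write_text("\t".join(bad))
        with pytest.raises(ValueError, match=":1"):
            parse_hits_m8(p)

    def test_write_parse_roundtrip(self, tmp_path, rng):
        hits = []
        for i in range(200):
            t_len = int(rng.integers(80, 200))
            span = int(rng.integers(40, t_len))
            hits.append(
                _hit(
                    target_id=f"t{i}",
                    t_len=t_len,
                    t_start=1,
                    t_end=span,
                    evalue=float(10.0 ** rng.uniform(-50, 0)),
                    percent_identity=float(np.round(rng.uniform(20, 99), 3)),
                )
            )
        p = tmp_path / "h.m8"
        write_hits_m8(hits, p)
        back = parse_hits_m8(p)
        assert len(back) == 200
        for a, b in zip(back, hits):
            assert a.target_id == b.target_id
            assert a.t_end == b.t_end and a.t_len == b.t_len
            assert a.percent_identity == pytest.approx(b.percent_identity, abs=1e-3)
            assert a.evalue == pytest.approx(b.evalue, rel=1e-3)


class TestFilterHits:
    def test_evalue_boundary_strict(self):
        assert filter_hits([_hit(evalue=1e-3)]) == []
        assert len(filter_hits([_hit(evalue=0.99e-3)])) == 1

    def test_full_coverage_low_evalue_kept(self):
        assert len(filter_hits([_hit(evalue=1e-10)])) == 1

    def test_coverage_boundary_inclusive(self):
        h = _hit(q_end=90, t_end=90)  # exactly 90% on both sides
        assert len(filter_hits([h])) == 1
        assert filter_hits([_hit(q_end=89)]) == []

    def test_missing_lengths_rejected(self):
        with pytest.raises(ValueError, match="lengths"):
            filter_hits([_hit(q_len=None)])

    def test_matches_independent_predicate_on_random_hits(self, rng):
        hits = []
        for i in range(500):
            q_len = int(rng.integers(50, 200))
            t_len = int(rng.integers(50, 200))
            q_start = int(rng.integers(1, q_len // 2))
            t_start = int(rng.integers(1, t_len // 2))
            hits.append(
                _hit(
                    target_id=f"t{i}",
                    q_len=q_len, t_len=t_len,
                    q_start=q_start, q_end=int(rng.integers(q_start, q_len + 1)),
                    t_start=t_start, t_end=int(rng.integers(t_start, t_len + 1)),
                    evalue=float(10.0 ** rng.uniform(-8, 0)),
                )
            )
        kept = filter_hits(hits)
        # independently coded predicate, applied per hit
        expected = [
            h for h in hits
            if h.evalue < 1e-3
            and (h.q_end - h.q_start + 1) / h.q_len >= 0.9
            and (h.t_end - h.t_start + 1) / h.t_len >= 0.9
        ]
        assert [h.target_id for h in kept] == [h.target_id for h in expected]

    def test_subset_and_idempotent(self, tmp_path):
        content, _ = generate_toy_hits(seed=3, n=60, frac_fail_evalue=0.3, frac_fail_cov=0.3)
        p = tmp_path / "h.m8"
        p.write_text(content)
        hits = parse_hits_m8(p)
        once = filter_hits(hits)
        assert set(h.target_id for h in once) <= set(h.target_id for h in hits)
        twice = filter_hits(once)
        assert [h.target_id for h in twice] == [h.target_id for h in once]


class TestPairwiseIdentity:
    def test_identical_sequences(self):
        a = SequenceRecord("a", "MKVLAWGHED")
        assert pairwise_identity(a, a) == 1.0

    def test_single_mismatch_length_ten(self):
        a = SequenceRecord("a", "AAAAAAAAAA")
        b = SequenceRecord("b", "AAAAAAAAAC")
        assert pairwise_identity(a, b) == pytest.approx(0.9)

    def test_symmetric(self, rng):
        for _ in range(5):
            a = SequenceRecord("a", "".join(rng.choice(_AA, size=30)))
            b = SequenceRecord("b", "".join(rng.choice(_AA, size=25)))
            assert pairwise_identity(a, b) == pytest.approx(
                pairwise_identity(b, a), abs=1e-12
            )

    def test_one_iff_identical(self, rng):
        a = SequenceRecord("a", "".join(rng.choice(_AA, size=30)))
        b = SequenceRecord("b", a.sequence[:-1] + ("A" if a.sequence[-1] != "A" else "C"))
        assert pairwise_identity(a, b) < 1.0

    def test_gap_counts_in_denominator(self):
        a = SequenceRecord("a", "MKVLAWGHED")
        b = SequenceRecord("b", "MKVLAWGHE")  # one terminal deletion
        assert pairwise_identity(a, b) == pytest.approx(0.9)


def _mutant(rng, seed_seq, max_frac):
    n_mut = int(rng.integers(0, max(1, int(len(seed_seq) * max_frac)) + 1))
    s = list(seed_seq)
    for p in rng.choice(len(s), size=n_mut, replace=False):
        alt = [a for a in _AA if a != s[p]]
        s[p] = alt[rng.integers(19)]
    return "".join(s)


class TestRedundancyFilter:
    def test_identical_pair_one_representative(self):
        recs = [SequenceRecord("b", "MKVLAWGHED"), SequenceRecord("a", "MKVLAWGHED")]
        reps, assignment = redundancy_filter(recs)
        assert len(reps) == 1 and reps[0].id == "a"  # id ascending at equal length
        assert assignment == {"a": "a", "b": "a"}

    def test_threshold_one_keeps_distinct(self, rng):
        recs = [
            SequenceRecord(f"s{i}", "".join(rng.choice(_AA, size=40)))
            for i in range(5)
        ]
        reps, _ = redundancy_filter(recs, threshold=1.0)
        assert len(reps) == 5

    def test_planted_clusters_recovered(self, rng):
        # 8 well-separated seed sequences, 5 members each within 5% mutations
        seeds = []
        while len(seeds) < 8:
            cand = "".join(rng.choice(_AA, size=100))
            if all(
                pairwise_identity(SequenceRecord("x", cand), SequenceRecord("y", s)) < 0.5
                for s in seeds
            ):
                seeds.append(cand)
        records, truth = [], {}
        k = 0
        for ci, seed_seq in enumerate(seeds):
            for _ in range(5):
                rec = SequenceRecord(f"m{k:02d}", _mutant(rng, seed_seq, 0.05))
                records.append(rec)
                truth[rec.id] = ci
                k += 1
        reps, assignment = redundancy_filter(records, threshold=0.9)
        assert len(reps) == 8
        # assignment groups must coincide with generating clusters
        rep_cluster = {r.id: truth[r.id] for r in reps}
        for rec_id, rep_id in assignment.items():
            assert truth[rec_id] == rep_cluster[rep_id]

    def test_every_member_close_to_its_representative(self, rng):
        seed_seq = "".join(rng.choice(_AA, size=60))
        records = [
            SequenceRecord(f"m{i}", _mutant(rng, seed_seq, 0.08)) for i in range(12)
        ]
        reps, assignment = redundancy_filter(records, threshold=0.9)
        by_id = {r.id: r for r in records}
        for rec_id, rep_id in assignment.items():
            if rec_id != rep_id:
                ident = pairwise_identity(by_id[rec_id], by_id[rep_id])
                assert ident >= 0.9


class TestRankCandidates:
    def _model_and_embeddings(self, records, values, seed=0):
        # pad with filler records so 1-NN memorization is trainable on tiny
        # candidate panels; exact-match queries still return planted values
        rng = np.random.default_rng(seed + 900)
        filler = [
            SequenceRecord(f"fill{i}", "".join(rng.choice(_AA, size=25)))
            for i in range(8)
        ]
        train_records = list(records) + filler
        emb_train = embed_dataset(train_records, SurrogateEmbedder(seed=seed), 1)
        y = np.concatenate([np.asarray(values, float), rng.normal(size=len(filler))])
        spec = RegressorSpec("knn", grid={"n_neighbors": [1]}, cv_folds=2, seed=seed)
        model = grid_search_train(emb_train.X, y, spec, train_ids=[r.id for r in train_records])
        emb = embed_dataset(records, SurrogateEmbedder(seed=seed), 1)
        return model, emb

    def test_order_follows_predictions(self, rng):
        records = [
            SequenceRecord(i, "".join(rng.choice(_AA, size=25)))
            for i in ("a", "b", "c")
        ]
        model, emb = self._model_and_embeddings(records, np.array([2.0, 1.0, 3.0]))
        ranked = rank_candidates(model, emb, records)
        assert [c.id for c in ranked] == ["c", "a", "b"]
        assert [c.rank for c in ranked] == [1, 2, 3]

    def test_tie_broken_by_id(self, rng):
        seq = "".join(rng.choice(_AA, size=25))
        records = [SequenceRecord(i, seq) for i in ("z", "m", "a")]
        model, emb = self._model_and_embeddings(records, np.array([1.0, 1.0, 1.0]))
        ranked = rank_candidates(model, emb, records)
        assert [c.id for c in ranked] == ["a", "m", "z"]

    def test_missing_embedding_rejected(self, rng):
        records = [SequenceRecord("a", "".join(rng.choice(_AA, size=25)))]
        model, emb = self._model_and_embeddings(records, np.array([1.0]))
        extra = records + [SequenceRecord("b", "".join(rng.choice(_AA, size=25)))]
        with pytest.raises(KeyError, match="b"):
            rank_candidates(model, emb, extra)

    def test_matches_independent_sort(self, rng):
        records = [
            SequenceRecord(f"c{i:03d}", "".join(rng.choice(_AA, size=30)))
            for i in range(100)
        ]
        values = rng.normal(size=100)
        model, emb = self._model_and_embeddings(records, values)
        ranked = rank_candidates(model, emb, records)
        from enzrank.regression import predict

        preds = predict(model, emb.rows_for([r.id for r in records]))
        expected = [
            records[i].id
            for i in sorted(range(100), key=lambda i: (-preds[i], records[i].id))
        ]
        assert [c.id for c in ranked] == expected
        assert sorted(c.rank for c in ranked) == list(range(1, 101))
        diffs = np.diff([c.predicted_value for c in ranked])
        assert np.all(diffs <= 1e-12)


class TestIdentityVsPrediction:
    def test_top1_self(self, rng):
        query = SequenceRecord("q", "".join(rng.choice(_AA, size=30)))
        records = [SequenceRecord("q2", query.sequence)]
        model, emb = TestRankCandidates()._model_and_embeddings(records, np.array([1.0]))
        ranked = rank_candidates(model, emb, records)
        summary = identity_vs_prediction(ranked, query, records, top_k=1)
        assert summary.min_identity == summary.max_identity == 1.0

    def test_degenerate_all_equal_no_crash(self, rng):
        query = SequenceRecord("q", "".join(rng.choice(_AA, size=30)))
        records = [SequenceRecord(f"c{i}", query.sequence) for i in range(4)]
        model, emb = TestRankCandidates()._model_and_embeddings(
            records, np.array([1.0, 1.0, 1.0, 1.0])
        )
        ranked = rank_candidates(model, emb, records)
        summary = identity_vs_prediction(ranked, query, records, top_k=4)
        assert summary.rank_identity_rho is None

    def test_planted_identity_gradient(self, rng):
        # candidates at increasing mutational distance from the query
        query = SequenceRecord("q", "".join(rng.choice(_AA, size=60)))
        records = []
        for i, n_mut in enumerate([0, 6, 12, 24]):
            s = list(query.sequence)
            for p in rng.choice(60, size=n_mut, replace=False):
                alt = [a for a in _AA if a != s[p]]
                s[p] = alt[rng.integers(19)]
            records.append(SequenceRecord(f"c{i}", "".join(s)))
        model, emb = TestRankCandidates()._model_and_embeddings(
            records, np.array([4.0, 3.0, 2.0, 1.0])
        )
        ranked = rank_candidates(model, emb, records)
        summary = identity_vs_prediction(ranked, query, records, top_k=4)
        brute = [pairwise_identity(r, query) for r in records]
        assert summary.min_identity == pytest.approx(min(brute))
        assert summary.max_identity == pytest.approx(max(brute))
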