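import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from asvembed.fixtures import CommunityModel, QueryDerivation, make_queries, make_reference
from asvembed.io_formats import AlignmentHit, CountTable, EmbeddingMatrix, SequenceSet, ValidationError
from asvembed.transform import (
    BestHitFilterConfig,
    HitAssignment,
    align_queries,
    embed_dataset,
    filter_best_hits,
    project,
    prune_embedding,
    relabel_counts,
)


def _kmer_set(seq, k=11):
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def identity_matrix(feature_ids) -> EmbeddingMatrix:
    return EmbeddingMatrix(
        pd.DataFrame(
            np.eye(len(feature_ids)),
            index=list(feature_ids),
            columns=[f"d{i}" for i in range(len(feature_ids))],
        ),
        method="glove",
    )


class TestBuiltinAligner:
    def test_self_match_full_identity(self, tiny_reference):
        seqs, _ = tiny_reference
        first = seqs.ids[0]
        query = SequenceSet({"q": seqs[first]})
        hits = align_queries(query, seqs, engine="builtin")
        self_hits = [h for h in hits if h.subject_id == first]
        assert len(self_hits) == 1
        assert self_hits[0].percent_identity == 100.0
        assert self_hits[0].alignment_length == 253
        assert self_hits[0].evalue < 1e-40

    def test_no_shared_kmer_means_no_hits(self, tiny_reference):
        seqs, _ = tiny_reference
        query_seq = "AC" * 126 + "A"  # 253 bp of dinucleotide repeat
        assert all(
            not (_kmer_set(query_seq) & _kmer_set(s))
            for s in seqs.sequences.values()
        )
        hits = align_queries(SequenceSet({"q": query_seq}), seqs, engine="builtin")
        assert hits == []

    def test_single_internal_mismatch_identity(self, tiny_reference):
        seqs, _ = tiny_reference
        first = seqs.ids[0]
        mutated = list(seqs[first])
        mutated[120] = {"A": "C", "C": "G", "G": "T", "T": "A"}[mutated[120]]
        hits = align_queries(SequenceSet({"q": "".join(mutated)}), seqs)
        hit = next(h for h in hits if h.subject_id == first)
        assert round(hit.percent_identity, 1) == 99.6  # 252/253
        assert hit.alignment_length == 253

    def test_empty_reference_rejected(self):
        with pytest.raises(ValidationError, match="empty"):
            align_queries(SequenceSet({"q": "ACGT"}), SequenceSet({}))

    def test_external_blast_satisfies_same_contract(self, tiny_reference):
        """BLAST+ and the builtin engine agree on which reference each
        mutated query best-matches, not on the exact numbers."""
        pytest.importorskip("shutil")
        import shutil

        if shutil.which("blastn") is None:
            pytest.skip("BLAST+ not on PATH")
        seqs, _ = tiny_reference
        queries, truth = make_queries(
            seqs, QueryDerivation(seqs.ids[:5], mutation_rate=0.01, seed=9)
        )
        for engine in ("builtin", "external_blast"):
            assignments = filter_best_hits(align_queries(queries, seqs, engine=engine))
            mapped = {a.query_id: a.subject_ids for a in assignments}
            for qid, src in truth.items():
                assert mapped[qid] == (src,), engine


def hit(q, s, e, pid, length):
    return AlignmentHit(q, s, pid, length, e)


class TestBestHitFilter:
    def test_evalue_ceiling_drops_query(self):
        assert filter_best_hits([hit("q", "s", 1e-30, 100.0, 253)]) == []

    def test_evalue_ranks_before_identity(self):
        hits = [
            hit("q", "s1", 1e-60, 99.0, 250),
            hit("q", "s2", 1e-50, 100.0, 253),
        ]
        (a,) = filter_best_hits(hits)
        assert a.subject_ids == ("s1",) and a.weight == 1.0

    def test_exactly_one_hundred_ties_kept(self):
        hits = [hit("q", f"s{i}", 1e-50, 99.0, 250) for i in range(100)]
        (a,) = filter_best_hits(hits)
        assert len(a.subject_ids) == 100

    def test_over_one_hundred_ties_dropped(self):
        hits = [hit("q", f"s{i}", 1e-50, 99.0, 250) for i in range(101)]
        assert filter_best_hits(hits) == []

    def test_two_way_tie_splits_weight(self):
        hits = [hit("q", "s1", 1e-50, 99.0, 250), hit("q", "s2", 1e-50, 99.0, 250)]
        (a,) = filter_best_hits(hits)
        assert a.subject_ids == ("s1", "s2") and a.weight == 0.5

    def test_identity_floor_applied_before_ranking(self):
        hits = [
            hit("q", "low", 1e-80, 96.9, 253),  # best E but below floor
            hit("q", "ok", 1e-50, 98.0, 250),
        ]
        (a,) = filter_best_hits(hits)
        assert a.subject_ids == ("ok",)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.integers(0, 2**31 - 1))
    def test_agrees_with_bruteforce_sort_oracle(self, seed):
        rng = np.random.default_rng(seed)
        hits = []
        for _ in range(rng.integers(1, 500)):
            q = f"q{rng.integers(8)}"
            s = f"s{rng.integers(30)}"
            e = float(rng.choice([1e-60, 1e-50, 1e-45, 1e-30]))
            pid = float(rng.choice([96.0, 97.0, 99.0, 100.0]))
            length = int(rng.choice([240, 250, 253]))
            hits.append(hit(q, s, e, pid, length))
        cfg = BestHitFilterConfig()
        got = {a.query_id: set(a.subject_ids) for a in filter_best_hits(hits, cfg)}

        # oracle: per query sort by the triple key, take the tied head
        expected = {}
        for q in {h.query_id for h in hits}:
            survivors = [
                h
                for h in hits
                if h.query_id == q
                and h.evalue <= cfg.max_evalue
                and h.percent_identity >= cfg.min_percent_identity
            ]
            if not survivors:
                continue
            key = lambda h: (h.evalue, -h.percent_identity, -h.alignment_length)
            head = sorted(survivors, key=key)[0]
            tied = {h.subject_id for h in survivors if key(h) == key(head)}
            if len(tied) <= cfg.max_ties:
                expected[q] = tied
        assert got == expected


class TestRelabelCounts:
    def test_three_way_split(self):
        table = CountTable(pd.DataFrame([[9.0]], index=["s"], columns=["q"]))
        out = relabel_counts(table, [HitAssignment("q", ("a", "b", "c"))])
        assert out.data.loc["s"].tolist() == [3.0, 3.0, 3.0]

    def test_two_queries_same_subject_accumulate(self):
        table = CountTable(
            pd.DataFrame([[2.0, 5.0]], index=["s"], columns=["q1", "q2"])
        )
        out = relabel_counts(
            table, [HitAssignment("q1", ("s1",)), HitAssignment("q2", ("s1",))]
        )
        assert out.data.loc["s", "s1"] == 7.0

    def test_unassigned_query_mass_dropped(self):
        table = CountTable(
            pd.DataFrame([[4.0, 6.0]], index=["s"], columns=["q1", "q2"])
        )
        out = relabel_counts(table, [HitAssignment("q2", ("s1", "s2"))])
        assert out.values().sum() == pytest.approx(table.values().sum() - 4.0)

    def test_unknown_query_id_rejected(self):
        table = CountTable(pd.DataFrame([[1.0]], index=["s"], columns=["q"]))
        with pytest.raises(ValidationError, match="unknown query"):
            relabel_counts(table, [HitAssignment("nope", ("s1",))])

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(st.integers(0, 2**31 - 1))
    def test_mass_conservation_on_random_fixtures(self, seed):
        rng = np.random.default_rng(seed)
        n_q, n_s = int(rng.integers(1, 10)), 4
        table = CountTable(
            pd.DataFrame(
                rng.integers(0, 50, size=(3, n_q)).astype(float),
                index=["a", "b", "c"],
                columns=[f"q{i}" for i in range(n_q)],
            )
        )
        assigned = [f"q{i}" for i in range(n_q) if rng.random() < 0.7]
        assignments = [
            HitAssignment(
                q,
                tuple(
                    f"s{j}"
                    for j in rng.choice(n_s, size=rng.integers(1, n_s), replace=False)
                ),
            )
            for q in assigned
        ]
        out = relabel_counts(table, assignments)
        expected_mass = table.data[assigned].to_numpy().sum()
        assert abs(out.values().sum() - expected_mass) < 1e-9


class TestPruneAndProject:
    def test_prune_identity_and_order(self):
        m = identity_matrix(["a", "b", "c"])
        assert prune_embedding(m, ["a", "b", "c"]).feature_ids == ["a", "b", "c"]
        assert prune_embedding(m, ["c", "a"]).feature_ids == ["c", "a"]
        assert prune_embedding(m, []).values().shape == (0, 3)

    def test_prune_unknown_id_rejected(self):
        with pytest.raises(ValidationError, match="absent"):
            prune_embedding(identity_matrix(["a"]), ["zzz"])

    def test_hand_dot_product(self):
        table = CountTable(
            pd.DataFrame([[1.0, 2.0, 3.0]], index=["s"], columns=["a", "b", "c"])
        )
        m = EmbeddingMatrix(
            pd.DataFrame(
                [[1.0, 0.0], [0.0, 1.0], [1.0, 1.0]],
                index=["a", "b", "c"],
                columns=["d0", "d1"],
            ),
            method="glove",
        )
        out = project(table, m, normalize=False)
        assert out.values().tolist() == [[4.0, 5.0]]

    def test_zero_counts_embed_to_zero(self):
        table = CountTable(
            pd.DataFrame(np.zeros((2, 3)), index=["s1", "s2"], columns=["a", "b", "c"])
        )
        out = project(table, identity_matrix(["a", "b", "c"]))
        assert not out.values().any()

    def test_identity_matrix_returns_normalized_input(self, small_counts):
        out = project(small_counts, identity_matrix(small_counts.feature_ids))
        assert np.allclose(out.values(), np.arcsinh(small_counts.values()))

    def test_feature_mismatch_lists_ids(self, small_counts):
        with pytest.raises(ValidationError, match="X"):
            project(small_counts, identity_matrix(["A", "B", "X"]))

    def test_linearity_without_normalization(self):
        rng = np.random.default_rng(4)
        values = rng.random((2, 5)) * 10
        table = CountTable(
            pd.DataFrame(
                np.vstack([values, values.sum(axis=0)]),
                index=["a", "b", "a+b"],
                columns=[f"f{i}" for i in range(5)],
            )
        )
        m = EmbeddingMatrix(
            pd.DataFrame(
                rng.normal(size=(5, 3)),
                index=[f"f{i}" for i in range(5)],
                columns=["d0", "d1", "d2"],
            ),
            method="glove",
        )
        out = project(table, m, normalize=False).values()
        assert np.abs(out[0] + out[1] - out[2]).max() < 1e-9


class TestEmbedDataset:
    def test_end_to_end_identity(self, tiny_reference):
        seqs, counts = tiny_reference
        embedded, report = embed_dataset(
            seqs, counts, seqs, identity_matrix(counts.feature_ids)
        )
        assert report["n_aligned"] == report["n_queries"] == len(seqs)
        assert embedded.data.shape == counts.data.shape
        assert report["mean_subjects_per_query"] == 1.0

    def test_identity_values_match_normalized_counts(self, tiny_reference):
        seqs, counts = tiny_reference
        matrix = identity_matrix(counts.feature_ids)
        embedded, _ = embed_dataset(seqs, counts, seqs, matrix)
        # identity matrix: dimension d{i} carries feature i's normalized count
        dim_for_feature = {f: f"d{i}" for i, f in enumerate(counts.feature_ids)}
        for f in counts.feature_ids:
            assert np.allclose(
                embedded.data[dim_for_feature[f]].to_numpy(),
                np.arcsinh(counts.data[f].to_numpy()),
            )

    def test_tie_report_statistics(self):
        """3 queries with 1, 2 and 3 tied subjects: mean 2, median 2."""
        seqs = SequenceSet({f"r{i}": "ACGT" * 64 for i in range(1)})
        table = CountTable(
            pd.DataFrame(
                [[1.0, 1.0, 1.0]], index=["s"], columns=["q1", "q2", "q3"]
            )
        )
        hits = (
            [hit("q1", "a", 1e-50, 99.0, 250)]
            + [hit("q2", s, 1e-50, 99.0, 250) for s in ("a", "b")]
            + [hit("q3", s, 1e-50, 99.0, 250) for s in ("a", "b", "c")]
        )
        matrix = identity_matrix(["a", "b", "c"])
        _, report = embed_dataset(
            SequenceSet({q: "ACGT" * 64 for q in ("q1", "q2", "q3")}),
            table,
            seqs,
            matrix,
            hits=hits,
        )
        assert report["mean_subjects_per_query"] == 2.0
        assert report["median_subjects_per_query"] == 2.0
        assert report["max_evalue_accepted"] == 1e-50
        assert report["min_alignment_length_accepted"] == 250

    def test_identity_threshold_monotone_in_assigned_queries(self, tiny_reference):
        """Raising the identity floor never increases the number of
        aligned queries (97 -> 99 -> 100 on 1%-mutated queries)."""
        seqs, _ = tiny_reference
        queries, _ = make_queries(
            seqs, QueryDerivation(list(seqs.ids), mutation_rate=0.01, seed=2)
        )
        hits = align_queries(queries, seqs)
        counts = [
            len(filter_best_hits(hits, BestHitFilterConfig(min_percent_identity=t)))
            for t in (97.0, 99.0, 100.0)
        ]
        assert counts[0] >= counts[1] >= counts[2]
        assert counts[0] > 0

    def test_mutation_rate_at_threshold_matches_aligner_oracle(self, tiny_reference):
        """The reported alignment rate equals a brute-force count of
        queries whose best hit clears the identity floor."""
        seqs, counts_table = tiny_reference
        queries, truth = make_queries(
            seqs, QueryDerivation(list(seqs.ids), mutation_rate=0.01, seed=13)
        )
        table = CountTable(
            pd.DataFrame(
                np.ones((2, len(queries))),
                index=["s1", "s2"],
                columns=list(queries.ids),
            )
        )
        cfg = BestHitFilterConfig(min_percent_identity=97.0)
        _, report = embed_dataset(
            queries, table, seqs, identity_matrix(seqs.ids), cfg=cfg
        )
        # oracle: exhaustively align every query to every reference
        hits = align_queries(queries, seqs)
        best = {}
        for h in hits:
            if h.evalue <= cfg.max_evalue and h.percent_identity >= 97.0:
                best.setdefault(h.query_id, 0)
                best[h.query_id] += 1
        assert report["n_aligned"] == len(best)
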