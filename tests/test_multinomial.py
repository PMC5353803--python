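"""Multinomial training and streaming classification."""

import numpy as np
import pytest

import microtax as mt
from microtax.multinomial import (
    aggregate_taxon_counts,
    breakeven_word_length,
    classify_streaming,
    predict_taxa,
    train_multinomial,
)
from microtax.seqcodec import count_kmers, encode_sequence


def _enc(*seqs):
    return [encode_sequence(s) for s in seqs]


class TestAggregate:
    def test_single_sequence(self):
        X = aggregate_taxon_counts(_enc("AAAA"), ["T1"], k=1)
        assert X.X.tolist() == [[4, 0, 0, 0]]

    def test_counts_sum_within_taxon(self):
        X = aggregate_taxon_counts(_enc("AC", "CA"), ["T1", "T1"], k=1)
        assert X.X.tolist() == [[2, 2, 0, 0]]

    def test_two_taxa_rows(self):
        X = aggregate_taxon_counts(_enc("AC", "GT"), ["T1", "T2"], k=1)
        assert X.X.tolist() == [[1, 1, 0, 0], [0, 0, 1, 1]]
        assert X.taxa == ["T1", "T2"]

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            aggregate_taxon_counts([], [], k=1)

    def test_all_alien_taxon_warns_but_kept(self):
        with pytest.warns(UserWarning, match="zero valid"):
            X = aggregate_taxon_counts(_enc("AC", "NNNN"), ["T1", "T2"], k=2)
        assert X.X[1].sum() == 0


class TestTrain:
    def test_worked_example(self):
        X = aggregate_taxon_counts(_enc("AACG"), ["T1"], k=1)
        # counts [2,1,1,0], P=4: probabilities (x + 1)/8
        Q = train_multinomial(X, 4.0)
        np.testing.assert_allclose(
            Q.Q[0], [np.log2(3 / 8), -2.0, -2.0, -3.0], atol=1e-12
        )

    def test_zero_row_uniform(self):
        with pytest.warns(UserWarning):
            X = aggregate_taxon_counts(_enc("NN"), ["T1"], k=1)
        Q = train_multinomial(X, 4.0)
        np.testing.assert_allclose(Q.Q[0], [-2.0] * 4, atol=1e-12)

    def test_pseudo_count_must_be_positive(self):
        X = aggregate_taxon_counts(_enc("ACGT"), ["T1"], k=1)
        with pytest.raises(ValueError):
            train_multinomial(X, 0.0)

    @pytest.mark.parametrize("k", [1, 2, 4])
    @pytest.mark.parametrize("pseudo", [1.0, 100.0])
    def test_rows_normalize(self, rng, k, pseudo):
        seqs = ["".join(rng.choice(list("ACGT"), 200)) for _ in range(6)]
        X = aggregate_taxon_counts(_enc(*seqs), ["A", "A", "B", "B", "C", "C"], k)
        Q = train_multinomial(X, pseudo)
        np.testing.assert_allclose((2.0**Q.Q).sum(axis=1), 1.0, atol=1e-9)
        assert (Q.Q < 0).all()


class TestClassify:
    def test_streaming_equals_count_vector_product(self, rng, flat_model):
        """Streaming summation must match explicit count-vector x Q^T scoring."""
        queries = _enc(*["".join(rng.choice(list("ACGT"), 50)) for _ in range(100)])
        scores = classify_streaming(queries, flat_model)
        for i, q in enumerate(queries):
            explicit = count_kmers(q, flat_model.k) @ flat_model.Q.T
            np.testing.assert_allclose(scores.scores[i], explicit, atol=1e-9)

    def test_toy_score_is_column_sum(self):
        X = aggregate_taxon_counts(_enc("ACCA", "GTTG"), ["T1", "T2"], k=2)
        Q = train_multinomial(X, 16.0)
        scores = classify_streaming(_enc("ACGT"), Q)
        np.testing.assert_allclose(
            scores.scores[0], Q.Q[:, [1, 6, 11]].sum(axis=1), atol=1e-12
        )

    def test_unscorable_query_flagged_not_dropped(self, flat_model):
        scores = classify_streaming(_enc("NNNNNNNNNN", "ACGT" * 30), flat_model)
        assert not scores.scorable[0] and scores.scorable[1]
        assert scores.scores.shape[0] == 2

    def test_single_taxon_model_always_wins(self):
        X = aggregate_taxon_counts(_enc("ACGTACGT"), ["only"], k=2)
        Q = train_multinomial(X, 1.0)
        with pytest.warns(UserWarning, match="single-taxon"):
            top = predict_taxa(classify_streaming(_enc("ACGTAC"), Q), Q.taxa)
        assert top.best_taxon(0) == "only"
        assert top.p2[0] == -np.inf


class TestPredict:
    def _scores(self, rows):
        from microtax.multinomial import PosteriorScores

        arr = np.asarray(rows, dtype=float)
        return PosteriorScores(
            scores=arr,
            lengths=np.full(arr.shape[0], 100),
            scorable=np.ones(arr.shape[0], dtype=bool),
        )

    def test_top_two(self):
        top = predict_taxa(self._scores([[-10, -12, -15]]), ["a", "b", "c"])
        assert (top.best_taxon(0), top.p1[0], top.p2[0]) == ("a", -10, -12)
        assert top.taxa[top.second_index[0]] == "b"

    def test_exact_tie_breaks_to_lowest_index(self):
        top = predict_taxa(self._scores([[-10, -10, -15]]), ["a", "b", "c"])
        assert top.best_taxon(0) == "a"
        assert top.tie[0]
        assert top.p1[0] == top.p2[0]


class TestProperties:
    def test_self_consistency_on_separated_genera(self, flat_community, flat_model):
        """Full-length training sequences recover their own genus when
        centroids are >= 10% divergent."""
        _, records, taxonomy = flat_community
        labels = dict(zip(taxonomy["sequence_id"], taxonomy["genus"]))
        queries = [encode_sequence(s) for _, s in records]
        top = predict_taxa(classify_streaming(queries, flat_model), flat_model.taxa)
        correct = [
            top.best_taxon(i) == labels[rid] for i, (rid, _) in enumerate(records)
        ]
        assert np.mean(correct) >= 0.99

    def test_longer_fragments_no_less_accurate(self, rng, flat_community, flat_model):
        _, records, taxonomy = flat_community
        labels = dict(zip(taxonomy["sequence_id"], taxonomy["genus"]))

        def accuracy(frag_len):
            queries, truth = [], []
            for rid, seq in records:
                start = int(rng.integers(0, len(seq) - frag_len + 1))
                queries.append(encode_sequence(seq[start : start + frag_len]))
                truth.append(labels[rid])
            top = predict_taxa(
                classify_streaming(queries, flat_model), flat_model.taxa
            )
            return np.mean([top.best_taxon(i) == t for i, t in enumerate(truth)])

        assert accuracy(500) >= accuracy(150)

    def test_streaming_operation_count_bound(self):
        """Number of column additions per query never exceeds n - K + 1."""
        enc = encode_sequence("ACGTN" * 40)
        k = 8
        assert mt.kmer_indices(enc, k).size <= len(enc) - k + 1


def test_breakeven_word_length_near_5_27():
    k = breakeven_word_length(1500)
    assert 4.0**k == pytest.approx(1500 - k, rel=1e-9)
    assert round(k, 2) == 5.27
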