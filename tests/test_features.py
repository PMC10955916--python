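import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from stressclust import (
    Corpus,
    Document,
    FeatureRanking,
    FilterThresholds,
    TfidfMatrix,
    build_term_document_matrix,
    compute_tfidf,
    filter_terms,
    rank_terms_by_mutual_information,
    restrict_vocabulary,
    select_top_fraction,
)


def corpus_from_tokens(token_lists, labels=None):
    docs = [
        Document(
            f"d{i}", " ".join(toks), tuple(toks),
            label=None if labels is None else labels[i],
        )
        for i, toks in enumerate(token_lists)
    ]
    return Corpus(docs)


def tfidf_from_weights(weights, vocab=None):
    weights = np.asarray(weights, float)
    vocab = vocab or tuple(f"t{j}" for j in range(weights.shape[1]))
    ids = tuple(f"d{i}" for i in range(weights.shape[0]))
    return TfidfMatrix(weights, tuple(vocab), ids, np.ones(weights.shape[1]))


token_corpora = st.lists(
    st.lists(st.sampled_from("abcdefgh"), min_size=1, max_size=12),
    min_size=2, max_size=8,
)


class TestTermDocumentMatrix:
    def test_direct_counting(self):
        tdm = build_term_document_matrix(corpus_from_tokens([["a", "b", "a"], ["b", "c"]]))
        assert tdm.vocabulary == ("a", "b", "c")
        np.testing.assert_array_equal(tdm.counts, [[2, 1, 0], [0, 1, 1]])

    def test_single_token(self):
        tdm = build_term_document_matrix(corpus_from_tokens([["x"]]))
        np.testing.assert_array_equal(tdm.counts, [[1]])

    def test_document_permutation_permutes_rows_only(self):
        lists = [["a", "b"], ["b", "c", "c"], ["a"]]
        tdm = build_term_document_matrix(corpus_from_tokens(lists))
        perm = [2, 0, 1]
        tdm_p = build_term_document_matrix(corpus_from_tokens([lists[i] for i in perm]))
        assert tdm_p.vocabulary == tdm.vocabulary
        np.testing.assert_array_equal(tdm_p.counts, tdm.counts[perm])

    def test_empty_corpus_rejected(self):
        with pytest.raises(ValueError, match="no tokens"):
            build_term_document_matrix(corpus_from_tokens([[]]))


class TestTfidf:
    def test_single_document_idf_is_one(self):
        tfidf = compute_tfidf(build_term_document_matrix(corpus_from_tokens([["a", "b", "b"]])))
        np.testing.assert_allclose(tfidf.idf, 1.0)
        assert math.isclose(np.linalg.norm(tfidf.weights[0]), 1.0, rel_tol=1e-9)

    def test_hand_computed_example(self):
        # idf(t) = ln((1+N)/(1+df)) + 1, rows L2-normalized
        corpus = corpus_from_tokens([["a", "a", "b"], ["b", "c"], ["c"]])
        tfidf = compute_tfidf(build_term_document_matrix(corpus))
        idf_a = math.log(4 / 2) + 1
        idf_bc = math.log(4 / 3) + 1
        np.testing.assert_allclose(tfidf.idf, [idf_a, idf_bc, idf_bc], rtol=1e-12)
        raw = np.array([2 * idf_a, 1 * idf_bc, 0.0])
        np.testing.assert_allclose(tfidf.weights[0], raw / np.linalg.norm(raw), rtol=1e-12)
        np.testing.assert_allclose(tfidf.weights[0][:2], [0.9347, 0.3554], atol=5e-5)

    @settings(max_examples=30, deadline=None)
    @given(token_corpora)
    def test_rows_unit_norm_and_deterministic(self, lists):
        corpus = corpus_from_tokens(lists)
        tfidf = compute_tfidf(build_term_document_matrix(corpus))
        norms = np.linalg.norm(tfidf.weights, axis=1)
        nonempty = np.array([len(t) > 0 for t in lists])
        np.testing.assert_allclose(norms[nonempty], 1.0, atol=1e-9)
        again = compute_tfidf(build_term_document_matrix(corpus))
        assert (again.weights == tfidf.weights).all()

    def test_filter_statistics_consistent(self, default_tfidf):
        np.testing.assert_allclose(
            default_tfidf.total_weight, default_tfidf.weights.sum(axis=0), atol=1e-9
        )
        assert (default_tfidf.max_weight <= default_tfidf.total_weight + 1e-12).all()


def brute_force_filter(weights, tau_total, tau_ratio):
    """Independent per-term evaluation of the two pruning rules."""
    keep = []
    for j in range(weights.shape[1]):
        col = weights[:, j]
        total = col.sum()
        if total >= tau_total and (total > 0 and col.max() / total >= tau_ratio):
            keep.append(j)
    return set(keep)


class TestFilterRules:
    def test_uniform_spread_discarded_as_common(self):
        tfidf = tfidf_from_weights(np.full((25, 1), 0.04))
        with pytest.raises(ValueError):
            filter_terms(tfidf)  # the only term is discarded
        # with a surviving companion column the reason is recorded
        w = np.zeros((25, 2))
        w[:, 0] = 0.04
        w[0, 1] = 0.6
        result = filter_terms(tfidf_from_weights(w))
        assert result.discarded == {"t0": "common"}

    def test_low_total_discarded_as_rare(self):
        w = np.zeros((5, 2))
        w[0, 0] = 0.3
        w[1, 1] = 0.9
        result = filter_terms(tfidf_from_weights(w))
        assert result.discarded == {"t0": "rare"}

    def test_kept_term(self):
        w = np.zeros((3, 1))
        w[0, 0], w[1, 0] = 0.4, 0.3  # total 0.7, ratio 0.571
        result = filter_terms(tfidf_from_weights(w))
        assert result.tfidf.vocabulary == ("t0",)
        assert result.discarded == {}

    def test_no_renormalization(self):
        w = np.zeros((3, 2))
        w[:, 0] = [0.4, 0.3, 0.0]
        w[0, 1] = 0.1  # rare, removed
        result = filter_terms(tfidf_from_weights(w))
        np.testing.assert_array_equal(result.tfidf.weights[:, 0], w[:, 0])

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        w = rng.random((6, 10)) * (rng.random((6, 10)) < 0.4)
        w[0, 0] = 1.0  # guarantee one survivor
        tfidf = tfidf_from_weights(w)
        thr = FilterThresholds(0.5, 0.1)
        result = filter_terms(tfidf, thr)
        kept = {tfidf.vocabulary.index(t) for t in result.tfidf.vocabulary}
        assert kept == brute_force_filter(w, thr.tau_total, thr.tau_ratio)

    def test_survivors_monotone_in_thresholds(self):
        rng = np.random.default_rng(7)
        w = rng.random((8, 15)) * (rng.random((8, 15)) < 0.5)
        w[0, 0] = 2.0
        tfidf = tfidf_from_weights(w)
        base = set(filter_terms(tfidf, FilterThresholds(0.3, 0.05)).tfidf.vocabulary)
        for tt, tr in [(0.5, 0.05), (0.3, 0.2), (0.6, 0.3)]:
            tighter = set(filter_terms(tfidf, FilterThresholds(tt, tr)).tfidf.vocabulary)
            assert tighter <= base

    def test_all_discarded_raises(self):
        with pytest.raises(ValueError, match="relax"):
            filter_terms(tfidf_from_weights(np.full((30, 3), 0.01)))


class TestMutualInformation:
    def test_constant_feature_zero(self):
        w = np.ones((6, 1))
        ranking = rank_terms_by_mutual_information(
            tfidf_from_weights(w), [0, 0, 0, 1, 1, 1]
        )
        assert ranking.scores[0] == pytest.approx(0.0, abs=1e-12)

    def test_perfect_association_one_bit(self):
        labels = [0, 0, 0, 1, 1, 1]
        w = np.array([[0.0], [0.0], [0.0], [0.5], [0.7], [0.2]])
        ranking = rank_terms_by_mutual_information(tfidf_from_weights(w), labels)
        assert ranking.scores[0] == pytest.approx(1.0, rel=1e-12)

    def test_independent_feature_zero(self):
        # present in 3 of 5 class-0 and 3 of 5 class-1 documents
        labels = [0] * 5 + [1] * 5
        col = np.array([1, 1, 1, 0, 0, 1, 1, 1, 0, 0], float)[:, None]
        ranking = rank_terms_by_mutual_information(tfidf_from_weights(col), labels)
        assert ranking.scores[0] == pytest.approx(0.0, abs=1e-12)

    def test_invariant_to_label_swap_and_doc_order(self):
        rng = np.random.default_rng(3)
        w = rng.random((10, 6)) * (rng.random((10, 6)) < 0.5)
        labels = np.array([0, 1] * 5)
        tfidf = tfidf_from_weights(w)
        r1 = rank_terms_by_mutual_information(tfidf, labels)
        r2 = rank_terms_by_mutual_information(tfidf, 1 - labels)
        perm = rng.permutation(10)
        r3 = rank_terms_by_mutual_information(tfidf_from_weights(w[perm]), labels[perm])
        for other in (r2, r3):
            assert other.terms == r1.terms
            np.testing.assert_allclose(other.scores, r1.scores, atol=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="classes"):
            rank_terms_by_mutual_information(tfidf_from_weights(np.ones((4, 1))), [1] * 4)

    def test_tie_break_lexicographic(self):
        w = np.array([[1.0, 1.0], [0.0, 0.0], [1.0, 1.0], [0.0, 0.0]])
        ranking = rank_terms_by_mutual_information(
            tfidf_from_weights(w, vocab=("zeta", "alpha")), [0, 0, 1, 1]
        )
        assert ranking.terms == ("alpha", "zeta")


class TestSelectTopFraction:
    def test_full_fraction_returns_everything(self):
        r = FeatureRanking(("a", "b", "c"), np.array([0.5, 0.2, 0.1]))
        assert select_top_fraction(r, 1.0) == ("a", "b", "c")

    def test_ceil_rounding(self):
        r = FeatureRanking(tuple("abcdefghij"), np.linspace(1, 0.1, 10))
        assert len(select_top_fraction(r, 0.25)) == 3

    def test_nested_selection(self):
        r = FeatureRanking(tuple("abcdefghij"), np.linspace(1, 0.1, 10))
        assert set(select_top_fraction(r, 0.2)) <= set(select_top_fraction(r, 0.4))

    @pytest.mark.parametrize("frac", [0.0, -0.1, 1.5])
    def test_invalid_fraction(self, frac):
        r = FeatureRanking(("a",), np.array([0.1]))
        with pytest.raises(ValueError):
            select_top_fraction(r, frac)


class TestRestrictVocabulary:
    def test_subset_and_unknown_term(self):
        tfidf = tfidf_from_weights(np.ones((2, 3)), vocab=("a", "b", "c"))
        sub = restrict_vocabulary(tfidf, ["c", "a"])
        assert sub.vocabulary == ("a", "c")
        with pytest.raises(KeyError):
            restrict_vocabulary(tfidf, ["zz"])
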