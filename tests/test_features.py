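"""Vectorization: tokenizer, bag-of-words, tf-idf, embeddings."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from epinews.features import (
    BowVector,
    EmbeddingModel,
    binarize,
    build_vocabulary,
    count_vector,
    document_embedding,
    load_embeddings,
    save_embeddings,
    tfidf_transform,
    tokenize,
    train_embeddings,
    word_matrix,
)

_tokens = st.lists(
    st.text(alphabet="abcdefghij", min_size=1, max_size=5), min_size=0, max_size=15
)


class TestTokenize:
    def test_lowercases_and_strips_punctuation(self):
        assert tokenize("500 cases of Cholera.") == ["500", "cases", "of", "cholera"]

    def test_empty(self):
        assert tokenize("") == []

    @given(_tokens)
    @settings(max_examples=50, deadline=None)
    def test_fixed_point_on_alphanumeric_tokens(self, tokens):
        assert tokenize(" ".join(tokens)) == tokens


class TestBagOfWords:
    def test_vocabulary_is_insertion_ordered_union(self):
        vocab = build_vocabulary([["a", "b", "c"], ["c", "d", "e"]])
        assert vocab.terms == ("a", "b", "c", "d", "e")
        assert len(vocab) == 5

    def test_empty_corpus(self):
        assert len(build_vocabulary([])) == 0

    def test_binary_and_count_by_definition(self):
        vocab = build_vocabulary([["a", "b", "c"]])
        assert binarize(["a", "a", "b"], vocab).values.tolist() == [1, 1, 0]
        assert count_vector(["a", "a", "b"], vocab).values.tolist() == [2, 1, 0]

    def test_all_oov_gives_zero_vector(self):
        vocab = build_vocabulary([["a"]])
        assert binarize(["z", "q"], vocab).values.tolist() == [0]

    @given(_tokens, _tokens)
    @settings(max_examples=50, deadline=None)
    def test_count_sum_conservation_and_binarize_consistency(self, train, doc):
        vocab = build_vocabulary([train])
        counts = count_vector(doc, vocab)
        in_vocab = sum(1 for t in doc if t in vocab)
        assert counts.values.sum() == in_vocab
        assert np.array_equal(binarize(doc, vocab).values, (counts.values > 0).astype(float))

    def test_binary_mode_rejects_other_values(self):
        with pytest.raises(ValueError):
            BowVector("binary", np.array([0.5]))


class TestTfidf:
    def test_hand_computed_two_document_corpus(self):
        vocab = build_vocabulary([["a", "a", "b"], ["a", "c"]])
        counts = [count_vector(["a", "a", "b"], vocab), count_vector(["a", "c"], vocab)]
        tfidf = tfidf_transform(counts)
        a, b, c = (vocab.index[t] for t in "abc")
        # a occurs in both docs: weight (2/2)*ln(2/2) = 0
        assert tfidf[0].values[a] == pytest.approx(0.0)
        # b occurs once in d1: (1/2)*ln(2/1)
        assert tfidf[0].values[b] == pytest.approx(0.5 * math.log(2), abs=1e-4)
        assert tfidf[0].values[b] == pytest.approx(0.3466, abs=1e-4)
        # c absent from d1
        assert tfidf[0].values[c] == 0.0

    def test_term_in_every_document_weighs_zero_everywhere(self):
        docs = [["x", "y"], ["x", "z"], ["x", "w"]]
        vocab = build_vocabulary(docs)
        tfidf = tfidf_transform([count_vector(d, vocab) for d in docs])
        i = vocab.index["x"]
        assert all(v.values[i] == pytest.approx(0.0) for v in tfidf)

    def test_empty_document_maps_to_zero_vector(self):
        vocab = build_vocabulary([["a"]])
        tfidf = tfidf_transform([count_vector(["a"], vocab), count_vector([], vocab)])
        assert not tfidf[1].values.any()


class TestTrainedEmbeddings:
    corpus = [
        ["cholera", "outbreak", "in", "nigeria"],
        ["measles", "outbreak", "in", "france"],
        ["cholera", "cases", "confirmed", "in", "nigeria"],
    ] * 3

    def test_coverage_dimension_and_self_similarity(self):
        model = train_embeddings(self.corpus, dimension=8, seed=0)
        terms = {t for doc in self.corpus for t in doc}
        assert set(model.vectors) == terms
        for term in terms:
            vec = model.vectors[term]
            assert vec.shape == (8,)
            norm = np.linalg.norm(vec)
            assert norm > 0
            assert float(vec @ vec) / norm**2 == pytest.approx(1.0)

    def test_min_count_excludes_rare_terms(self):
        model = train_embeddings(
            [["common", "common", "rare"], ["common", "common"]], dimension=4, min_count=2
        )
        assert "common" in model and "rare" not in model

    def test_deterministic_given_seed(self):
        a = train_embeddings(self.corpus, dimension=8, seed=5)
        b = train_embeddings(self.corpus, dimension=8, seed=5)
        for term in a.vectors:
            assert np.array_equal(a.vectors[term], b.vectors[term])

    def test_invalid_dimension_rejected(self):
        with pytest.raises(ValueError):
            train_embeddings(self.corpus, dimension=0)


class TestEmbeddingIO:
    def test_round_trip(self, tmp_path):
        model = EmbeddingModel(3, {"a": np.array([1.0, 2.0, 3.0]), "b": np.zeros(3)})
        path = tmp_path / "emb.txt"
        save_embeddings(model, path)
        loaded = load_embeddings(path)
        assert loaded.dimension == 3
        assert np.allclose(loaded.vectors["a"], [1, 2, 3])

    def test_header_line_accepted(self, tmp_path):
        path = tmp_path / "emb.txt"
        path.write_text("3 5\nw1 1 2 3 4 5\nw2 0 0 0 0 0\nw3 1 1 1 1 1\n")
        assert load_embeddings(path).dimension == 5

    def test_ragged_dimensions_rejected(self, tmp_path):
        path = tmp_path / "emb.txt"
        path.write_text("w1 1 2 3\nw2 1 2\n")
        with pytest.raises(ValueError, match="components"):
            load_embeddings(path)

    def test_empty_file_rejected(self, tmp_path):
        path = tmp_path / "emb.txt"
        path.write_text("")
        with pytest.raises(ValueError, match="empty"):
            load_embeddings(path)


class TestDocumentEmbedding:
    model = EmbeddingModel(
        2, {"a": np.array([1.0, 0.0]), "b": np.array([0.0, 1.0]), "c": np.array([-1.0, 0.0])}
    )

    def test_mean_of_one_is_that_vector(self):
        assert np.allclose(document_embedding(["a"], self.model), [1, 0])

    def test_opposite_vectors_cancel(self):
        assert np.allclose(document_embedding(["a", "c"], self.model), [0, 0])

    def test_componentwise_mean_ignoring_oov(self):
        emb = document_embedding(["a", "b", "c", "zzz"], self.model)
        assert np.allclose(emb, [0.0, 1 / 3])

    def test_no_known_tokens_gives_zero_vector(self):
        assert np.allclose(document_embedding(["x", "y"], self.model), [0, 0])

    @given(st.permutations(["a", "b", "c", "a"]))
    @settings(max_examples=20, deadline=None)
    def test_permutation_invariance(self, tokens):
        assert np.allclose(
            document_embedding(tokens, self.model),
            document_embedding(["a", "a", "b", "c"], self.model),
        )


class TestWordMatrix:
    model = EmbeddingModel(2, {"a": np.array([1.0, 2.0])})

    def test_padding_beyond_real_tokens_is_zero(self):
        mat = word_matrix(["a"] * 10, self.model, max_len=400)
        assert mat.n_real_tokens == 10
        assert mat.rows.shape == (400, 2)
        assert not mat.rows[10:].any()

    def test_long_document_truncated(self):
        mat = word_matrix(["a"] * 500, self.model, max_len=400)
        assert mat.n_real_tokens == 400 and mat.rows.shape == (400, 2)

    def test_empty_document_all_zero(self):
        mat = word_matrix([], self.model, max_len=400)
        assert mat.n_real_tokens == 0 and not mat.rows.any()
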