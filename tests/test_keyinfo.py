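"""Key-entity filters: most-frequent heuristic and key-sentence naive Bayes.

The naive Bayes implementation is checked two independent ways: against
a brute-force Bayes-rule oracle computed directly from the training
formulae, and against scikit-learn's reference estimators on identical
feature matrices.
"""

import itertools
import math
from datetime import date as Date

import numpy as np
import pytest
from sklearn.naive_bayes import BernoulliNB, MultinomialNB

from epinews.annotate import EntityMention, annotate
from epinews.corpus import Article, GoldRecord
from epinews.features import binarize, build_vocabulary, count_vector
from epinews.keyinfo import (
    SentenceExample,
    build_sentence_dataset,
    extract_all,
    fit_naive_bayes,
    load_model,
    most_frequent_key,
    predict_key_probability,
    save_model,
    select_key_entity,
)
from epinews.metrics import key_extraction_accuracy
from epinews.pipeline import train_key_models


def mention(cls, value, start=0):
    return EntityMention(cls, str(value), start, start + 1, value)


class TestMostFrequent:
    def test_mode_of_first_three_geo(self):
        mentions = [mention("geo", v, i) for i, v in enumerate(["FR", "DE", "FR", "US"])]
        assert most_frequent_key(mentions, "geo", first_k=3) == "FR"

    def test_singleton(self):
        assert most_frequent_key([mention("disease", "cholera")], "disease") == "cholera"

    def test_tie_broken_by_earliest_first_occurrence(self):
        mentions = [mention("count", v, i) for i, v in enumerate([7, 9, 9, 7])]
        # 7 and 9 both occur twice; 7 occurs first
        assert most_frequent_key(mentions, "count") == 7

    def test_no_mentions_returns_none(self):
        assert most_frequent_key([], "geo") is None

    def test_other_classes_ignored(self):
        mentions = [mention("geo", "FR"), mention("disease", "cholera", 5)]
        assert most_frequent_key(mentions, "disease") == "cholera"


class TestSentenceDataset:
    def _doc(self, text, article_id="a1"):
        return annotate(Article(id=article_id, text=text))

    def test_exact_count_match_is_key(self):
        doc = self._doc("500 cases were confirmed. Earlier, 30 cases were suspected.")
        gold = [GoldRecord("a1", "Cholera", "Nigeria", Date(2018, 5, 10), 500, True)]
        examples = build_sentence_dataset([doc], gold, "count")
        labels = {e.sentence_index: e.label for e in examples}
        assert labels == {0: "key", 1: "not_key"}

    def test_date_within_three_day_window_is_key(self):
        doc = self._doc("Cases rose as of 2018-05-12. Nothing numeric here at all.")
        gold = [GoldRecord("a1", "Cholera", "Nigeria", Date(2018, 5, 10), 500, True)]
        examples = build_sentence_dataset([doc], gold, "date")
        assert [e.label for e in examples] == ["key"]

    def test_date_outside_window_is_not_key(self):
        doc = self._doc("Cases rose as of 2018-05-14.")
        gold = [GoldRecord("a1", "Cholera", "Nigeria", Date(2018, 5, 10), 500, True)]
        assert [e.label for e in build_sentence_dataset([doc], gold, "date")] == ["not_key"]

    def test_sentences_without_target_class_excluded(self):
        doc = self._doc("No numbers in this sentence. But 500 in this one.")
        gold = [GoldRecord("a1", "Cholera", "Nigeria", Date(2018, 5, 10), 500, True)]
        examples = build_sentence_dataset([doc], gold, "count")
        assert [e.sentence_index for e in examples] == [1]

    def test_article_without_gold_skipped(self, caplog):
        doc = self._doc("500 cases were confirmed.", article_id="orphan")
        assert build_sentence_dataset([doc], [], "count") == []


def _example(tokens, label, i=0):
    return SentenceExample("a", i, tuple(tokens), label)


TRAIN = [
    _example(["cases", "confirmed", "cholera"], "key", 0),
    _example(["confirmed", "deaths"], "key", 1),
    _example(["total", "cases", "reported"], "not_key", 2),
    _example(["reported", "earlier", "total"], "not_key", 3),
    _example(["update", "published", "total"], "not_key", 4),
]


def bernoulli_oracle(examples, tokens):
    """Brute-force Bayes rule from the Laplace-smoothed training formulae."""
    vocab = sorted({t for e in examples for t in e.tokens})
    joint = {}
    for label in ("key", "not_key"):
        members = [e for e in examples if e.label == label]
        prob = len(members) / len(examples)
        for term in vocab:
            n_with = sum(term in e.tokens for e in members)
            p = (n_with + 1) / (len(members) + 2)
            prob *= p if term in tokens else (1 - p)
        joint[label] = prob
    return joint["key"] / (joint["key"] + joint["not_key"])


class TestNaiveBayesOracle:
    def test_posterior_matches_brute_force_on_all_binary_sentences(self):
        model = fit_naive_bayes(TRAIN, "bernoulli")
        vocab = model.vocabulary.terms
        assert len(vocab) <= 10
        for r in range(len(vocab) + 1):
            for subset in itertools.combinations(vocab, r):
                expected = bernoulli_oracle(TRAIN, set(subset))
                assert predict_key_probability(model, list(subset)) == pytest.approx(
                    expected, abs=1e-12
                )

    def test_bernoulli_matches_sklearn_reference(self):
        model = fit_naive_bayes(TRAIN, "bernoulli")
        vocab = model.vocabulary
        x = np.stack([binarize(e.tokens, vocab).values for e in TRAIN])
        y = [e.label for e in TRAIN]
        ref = BernoulliNB(alpha=1.0).fit(x, y)
        key_col = list(ref.classes_).index("key")
        for e in TRAIN:
            ours = predict_key_probability(model, e.tokens)
            theirs = ref.predict_proba(
                binarize(e.tokens, vocab).values[None, :]
            )[0, key_col]
            assert ours == pytest.approx(theirs, abs=1e-9)

    def test_multinomial_matches_sklearn_on_tfidf_features(self):
        model = fit_naive_bayes(TRAIN, "multinomial")
        vocab = model.vocabulary
        counts = np.stack([count_vector(e.tokens, vocab).values for e in TRAIN])
        weighted = np.stack([model._tfidf(c) for c in counts])
        ref = MultinomialNB(alpha=1.0).fit(weighted, [e.label for e in TRAIN])
        key_col = list(ref.classes_).index("key")
        for row, e in zip(weighted, TRAIN):
            ours = predict_key_probability(model, e.tokens)
            theirs = ref.predict_proba(row[None, :])[0, key_col]
            assert ours == pytest.approx(theirs, abs=1e-9)

    @pytest.mark.parametrize("variant", ["bernoulli", "multinomial"])
    def test_label_swap_symmetry(self, variant):
        swapped = [
            _example(e.tokens, "key" if e.label == "not_key" else "not_key", e.sentence_index)
            for e in TRAIN
        ]
        model = fit_naive_bayes(TRAIN, variant)
        mirror = fit_naive_bayes(swapped, variant)
        for tokens in (["confirmed"], ["total", "reported"], ["cholera", "deaths"]):
            assert predict_key_probability(model, tokens) == pytest.approx(
                1.0 - predict_key_probability(mirror, tokens), abs=1e-12
            )

    def test_all_oov_sentence_gets_prior_driven_posterior(self):
        model = fit_naive_bayes(TRAIN, "bernoulli")
        assert predict_key_probability(model, ["zzz", "qqq"]) == pytest.approx(
            bernoulli_oracle(TRAIN, set()), abs=1e-12
        )
        # multinomial: zero weight vector -> posterior equals the prior
        model_m = fit_naive_bayes(TRAIN, "multinomial")
        assert predict_key_probability(model_m, ["zzz"]) == pytest.approx(
            math.exp(model_m.log_prior["key"]), abs=1e-12
        )

    def test_single_class_training_rejected(self):
        with pytest.raises(ValueError, match="both labels"):
            fit_naive_bayes([_example(["a"], "key")], "bernoulli")

    @pytest.mark.parametrize("variant", ["bernoulli", "multinomial"])
    def test_json_round_trip_preserves_predictions(self, tmp_path, variant):
        model = fit_naive_bayes(TRAIN, variant)
        path = tmp_path / "model.json"
        save_model(model, path)
        loaded = load_model(path)
        for e in TRAIN:
            assert predict_key_probability(loaded, e.tokens) == pytest.approx(
                predict_key_probability(model, e.tokens), abs=1e-12
            )


class TestSelectKeyEntity:
    def _trained_model(self):
        return fit_naive_bayes(TRAIN, "bernoulli")

    def test_argmax_sentence_supplies_the_value(self):
        doc = annotate(
            Article(
                id="a1",
                text="Earlier 10 cases were reported as total. Filler sentence without numbers. "
                "500 cases of cholera were confirmed.",
            )
        )
        model = self._trained_model()
        value, prob = select_key_entity(model, doc, "count")
        assert value == 500
        from epinews.features import tokenize

        probs = [predict_key_probability(model, tokenize(s)) for _, s in doc.sentences]
        assert prob == pytest.approx(max(probs[0], probs[2]), abs=1e-6)

    def test_single_candidate_returned_regardless_of_posterior(self):
        doc = annotate(Article(id="a1", text="Only 42 appear here as reported total."))
        value, prob = select_key_entity(self._trained_model(), doc, "count")
        assert value == 42 and 0.0 <= prob <= 1.0

    def test_none_when_no_mention_of_class(self):
        doc = annotate(Article(id="a1", text="No numeric facts at all."))
        assert select_key_entity(self._trained_model(), doc, "count") is None

    def test_first_mention_by_offset_within_argmax_sentence(self):
        doc = annotate(Article(id="a1", text="Both 7 and 9 were confirmed as cases."))
        value, _ = select_key_entity(self._trained_model(), doc, "count")
        assert value == 7


class TestEndToEndRecovery:
    def test_extract_all_recovers_gold_on_clean_synthetic_articles(
        self, small_corpus, small_docs
    ):
        date_model, count_model = train_key_models(small_docs, small_corpus.gold)
        predictions = {
            d.article.id: extract_all(d, date_model, count_model) for d in small_docs
        }
        accuracy = key_extraction_accuracy(predictions, small_corpus.gold)
        for cls in ("disease", "country", "date", "count"):
            assert accuracy[cls] >= 0.9, (cls, accuracy)
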