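"""The n-gram uncertainty scorer: counting, weighting, normalization."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _oracles import brute_force_ngram_counts, random_hedge_corpus
from eupkit.data_io import HedgeSentence
from eupkit.uncertainty_model import (
    F1,
    FeatureSpec,
    UncertaintyScorer,
    confidence,
    count_ngrams,
    default_feature_set,
    feature_score,
    fit_scorer,
    marker_probability,
)


class TestCounting:
    def test_hand_counted_example(self, toy_corpus):
        stats = count_ngrams(toy_corpus, kind="lemma", size=1)
        assert stats.get(("maybe",)) == (2, 2, 2)
        assert stats.get(("rain",)) == (2, 1, 0)
        assert stats.get(("no",)) == (1, 0, 0)
        assert stats.total_sentences == 3

    def test_certain_sentence_contributes_nothing_to_fu_fm(self):
        corpus = [HedgeSentence(["a", "b"], ["a", "b"], [0, 0], 0)]
        stats = count_ngrams(corpus, kind="token", size=1)
        for key in stats.counts:
            fs, fu, fm = stats.get(key)
            assert fu == 0 and fm == 0 and fs == 1

    def test_n_larger_than_longest_sentence_gives_empty_table(self, toy_corpus):
        assert count_ngrams(toy_corpus, kind="lemma", size=3).counts == {}

    def test_bigram_marker_requires_all_cues(self):
        corpus = [HedgeSentence(["might", "well", "might"], ["might", "well", "might"], [1, 0, 1], 1)]
        stats = count_ngrams(corpus, kind="lemma", size=2)
        assert stats.get(("might", "well")) == (1, 1, 0)

    def test_matches_bruteforce_on_random_corpora(self, rng):
        for _ in range(25):
            corpus = random_hedge_corpus(rng, int(rng.integers(1, 30)))
            for kind in ("lemma", "token"):
                for size in (1, 2):
                    stats = count_ngrams(corpus, kind=kind, size=size)
                    expected = brute_force_ngram_counts(corpus, kind, size)
                    assert {k: tuple(v) for k, v in stats.counts.items()} == expected

    def test_count_ordering_invariant(self, rng):
        corpus = random_hedge_corpus(rng, 40)
        stats = count_ngrams(corpus, kind="lemma", size=1)
        for key in stats.counts:
            fs, fu, fm = stats.get(key)
            assert fm <= fu <= fs


class TestProbabilities:
    def test_marker_probability_examples(self, toy_corpus):
        stats = count_ngrams(toy_corpus, kind="lemma", size=1)
        assert marker_probability(stats, "maybe") == 1.0
        assert marker_probability(stats, "rain") == 0.0
        assert marker_probability(stats, "unseen") == 0.0

    def test_marker_probability_fraction(self):
        corpus = [
            HedgeSentence(["might"], ["might"], [1], 1),
            HedgeSentence(["might"], ["might"], [1], 1),
            HedgeSentence(["might"], ["might"], [1], 1),
            HedgeSentence(["might", "x"], ["might", "x"], [0, 0], 0),
        ]
        stats = count_ngrams(corpus, kind="lemma", size=1)
        assert marker_probability(stats, "might") == pytest.approx(0.75)

    def test_confidence_closed_form(self, toy_corpus):
        stats = count_ngrams(toy_corpus, kind="lemma", size=1)
        assert confidence(stats, "unseen", 0.1) == 0.0
        assert confidence(stats, "no", 0.1) == pytest.approx(0.1)        # F_s = 1
        assert confidence(stats, "maybe", 0.1) == pytest.approx(1 - 0.9**2)

    def test_confidence_monotone_in_occurrences(self):
        many = [HedgeSentence(["w"], ["w"], [0], 0)] * 10 + [HedgeSentence(["u"], ["u"], [1], 1)]
        stats = count_ngrams(many, kind="lemma", size=1)
        assert confidence(stats, "w", 0.1) > confidence(stats, "u", 0.1)

    def test_confidence_rejects_bad_lambda(self, toy_corpus):
        stats = count_ngrams(toy_corpus, kind="lemma", size=1)
        for lam in (0.0, 1.0, -0.5):
            with pytest.raises(ValueError):
                confidence(stats, "maybe", lam)


class TestFeatureScore:
    def test_single_term_product(self):
        corpus = (
            [HedgeSentence(["maybe"], ["maybe"], [1], 1)] * 3
            + [HedgeSentence(["maybe"], ["maybe"], [0], 1)]
        )
        stats = count_ngrams(corpus, kind="lemma", size=1)
        # p = 3/4, conf = 1 - 0.9**4; a one-lemma sentence scores their product
        expected = 0.75 * (1 - 0.9**4)
        got = feature_score(stats, ["maybe"], ["maybe"], F1, 0.1)
        assert got == pytest.approx(expected, abs=1e-12)

    def test_empty_sentence_scores_zero(self, toy_corpus):
        stats = count_ngrams(toy_corpus, kind="lemma", size=1)
        for agg in ("sum", "mean", "max"):
            spec = FeatureSpec("lemma", 1, "uncertainty_marker", agg)
            assert feature_score(stats, [], [], spec, 0.1) == 0.0

    def test_aggregation_ordering(self, rng):
        stats = count_ngrams(random_hedge_corpus(rng, 30), kind="lemma", size=1)
        for _ in range(20):
            corpus = random_hedge_corpus(rng, 1)
            sentence = corpus[0]
            scores = {
                agg: feature_score(
                    stats, sentence.tokens, sentence.lemmas,
                    FeatureSpec("lemma", 1, "uncertainty_marker", agg), 0.1,
                )
                for agg in ("sum", "mean", "max")
            }
            assert scores["sum"] >= scores["max"] - 1e-12
            assert scores["max"] >= scores["mean"] - 1e-12

    def test_appending_strong_marker_never_decreases_sum_score(self, toy_corpus):
        scorer = fit_scorer(toy_corpus, confidence_lambda=0.1)
        stats = scorer.stats[("lemma", 1)]
        base = ["no", "rain"]
        spec = F1
        before = feature_score(stats, base, base, spec, 0.1)
        after = feature_score(stats, base + ["maybe"], base + ["maybe"], spec, 0.1)
        assert after >= before


class TestScorer:
    def test_unfitted_scorer_refuses_to_score(self, toy_corpus):
        scorer = fit_scorer(toy_corpus)
        scorer.norm_bounds = None
        with pytest.raises(RuntimeError, match="not fitted"):
            scorer.score("maybe rain")

    def test_unknown_vocabulary_scores_zero(self, toy_corpus):
        scorer = fit_scorer(toy_corpus)
        assert scorer.score("completely novel words here") == 0.0

    def test_training_extremes_hit_bounds(self):
        # one sentence dominates every feature's raw score, the other scores 0
        corpus = [
            HedgeSentence(["maybe", "maybe"], ["maybe", "maybe"], [1, 1], 1),
            HedgeSentence(["no", "rain"], ["no", "rain"], [0, 0], 0),
        ]
        scorer = fit_scorer(corpus)
        assert scorer.score("maybe maybe") == pytest.approx(1.0)
        assert scorer.score("no rain") == pytest.approx(0.0)

    def test_scores_order_by_hedging(self, toy_corpus):
        scorer = fit_scorer(toy_corpus)
        assert scorer.score("maybe rain") > scorer.score("no rain")

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.lists(st.sampled_from(["maybe", "rain", "no", "later", "zzz"]), max_size=12))
    def test_scores_bounded(self, words):
        corpus = [
            HedgeSentence(["maybe", "rain"], ["maybe", "rain"], [1, 0], 1),
            HedgeSentence(["maybe", "later"], ["maybe", "later"], [1, 0], 1),
            HedgeSentence(["no", "rain"], ["no", "rain"], [0, 0], 0),
        ]
        scorer = fit_scorer(corpus)
        assert 0.0 <= scorer.score(" ".join(words)) <= 1.0

    def test_refit_is_deterministic(self, rng):
        corpus = random_hedge_corpus(rng, 50)
        a = fit_scorer(corpus)
        b = fit_scorer(corpus)
        assert a.to_json() == b.to_json()

    def test_degenerate_corpora_rejected(self):
        certain = [HedgeSentence(["a"], ["a"], [0], 0)] * 3
        uncertain = [HedgeSentence(["m"], ["m"], [1], 1)] * 3
        with pytest.raises(ValueError, match="degenerate"):
            fit_scorer(certain)
        with pytest.raises(ValueError, match="degenerate"):
            fit_scorer(uncertain)
        with pytest.raises(ValueError, match="empty"):
            fit_scorer([])

    def test_serialization_round_trip(self, rng):
        corpus = random_hedge_corpus(rng, 60)
        scorer = fit_scorer(corpus)
        clone = UncertaintyScorer.from_json(scorer.to_json())
        for _ in range(10):
            text = " ".join(f"w{rng.integers(8)}" for _ in range(6))
            assert clone.score(text) == pytest.approx(scorer.score(text), abs=1e-12)

    def test_default_feature_set_contains_f1(self):
        assert F1 in default_feature_set()
        assert len(default_feature_set()) == 8

    def test_invalid_feature_spec(self):
        with pytest.raises(ValueError):
            FeatureSpec("stem", 1, "uncertainty_marker", "sum")
        with pytest.raises(ValueError):
            FeatureSpec("lemma", 4, "uncertainty_marker", "sum")
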