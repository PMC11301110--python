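"""Ensemble training, top-3 selection and the 2-of-3 vote."""

import itertools

import pytest
from hypothesis import given, strategies as st

import groupcohesion as gc
from groupcohesion.classifier import (
    CLASSIFIER_NAMES,
    NEGATIVE,
    POSITIVE,
    select_top3,
    vote,
)

#: published per-classifier F1 column used for selection arithmetic
PUBLISHED_F1 = {
    "svm": 0.63,
    "naive_bayes": 0.79,
    "mlp": 0.77,
    "random_forest": 0.72,
    "logistic_regression": 0.82,
}


class TestSelection:
    def test_top3_of_published_column(self):
        assert set(select_top3(PUBLISHED_F1)) == {
            "logistic_regression",
            "naive_bayes",
            "mlp",
        }

    def test_selected_mean_rounds_to_0_8(self):
        chosen = select_top3(PUBLISHED_F1)
        mean = sum(PUBLISHED_F1[n] for n in chosen) / 3
        assert round(mean, 1) == 0.8

    def test_tie_break_lexicographic(self):
        tied = {n: 0.5 for n in CLASSIFIER_NAMES}
        assert select_top3(tied) == sorted(CLASSIFIER_NAMES)[:3]


EQUAL_F1 = {"a": 0.8, "b": 0.8, "c": 0.8}


class TestVote:
    def test_majority_matches_brute_force_enumeration(self):
        for bits in itertools.product([0, 1], repeat=3):
            probs = dict(zip("abc", (float(b) for b in bits)))
            label, raw, conf = vote(probs, EQUAL_F1)
            expected = POSITIVE if sum(bits) >= 2 else NEGATIVE
            assert label == expected
            assert raw == pytest.approx(sum(bits) / 3)

    def test_all_zero_probabilities(self):
        label, raw, conf = vote({"a": 0.0, "b": 0.0, "c": 0.0}, EQUAL_F1)
        assert label == NEGATIVE and raw == 0.0 and conf == 1.0

    def test_two_of_three_positive(self):
        label, _, conf = vote({"a": 0.9, "b": 0.8, "c": 0.1}, EQUAL_F1)
        assert label == POSITIVE
        assert conf == pytest.approx(2 / 3)

    def test_weighted_confidence(self):
        f1 = {"a": 0.82, "b": 0.79, "c": 0.77}
        label, _, conf = vote({"a": 0.9, "b": 0.2, "c": 0.8}, f1)
        assert label == POSITIVE
        assert conf == pytest.approx((0.82 + 0.77) / (0.82 + 0.79 + 0.77))

    def test_wrong_arity_rejected(self):
        with pytest.raises(ValueError):
            vote({"a": 0.5, "b": 0.5}, EQUAL_F1)
        with pytest.raises(ValueError):
            vote({"a": 0.5, "b": 0.5, "c": 0.5, "d": 0.5}, EQUAL_F1)

    def test_out_of_range_probability_rejected(self):
        with pytest.raises(ValueError):
            vote({"a": 1.5, "b": 0.5, "c": 0.5}, EQUAL_F1)

    @given(
        st.tuples(*[st.floats(0, 1)] * 3),
        st.tuples(*[st.floats(0.05, 1)] * 3),
    )
    def test_confidence_bounds_and_unanimity(self, probs, f1s):
        probs = dict(zip("abc", probs))
        f1 = dict(zip("abc", f1s))
        labels = {n: p >= 0.5 for n, p in probs.items()}
        _, _, conf = vote(probs, f1)
        unanimous = len(set(labels.values())) == 1
        # confidence is at least the lightest possible 2-of-3 mass
        lo = min(
            (f1[a] + f1[b]) / sum(f1.values())
            for a, b in itertools.combinations("abc", 2)
        )
        assert lo - 1e-12 <= conf <= 1.0 + 1e-12
        assert (conf == pytest.approx(1.0)) == unanimous


class TestFit:
    def test_all_f1_beat_majority_baseline(self, fitted_model, small_corpus):
        # oracle: the majority class is non-cohesion, so its positive-class
        # F1 on any split is exactly 0
        majority_f1 = 0.0
        for name in CLASSIFIER_NAMES:
            assert fitted_model.val_f1[name] > max(majority_f1, 0.5)

    def test_feature_count_capped(self, fitted_model):
        n_vocab = len(fitted_model.vectorizer.vocabulary_)
        assert n_vocab <= 5000
        X = fitted_model._features(["we are friends"])
        assert X.shape[1] == n_vocab + 1  # +1 engineered lexicon feature

    def test_refit_same_seed_same_selection(self, small_corpus, cohesion_lexicon, fitted_model):
        again = gc.fit(small_corpus, seed=7, lexicon=cohesion_lexicon)
        assert again.selected == fitted_model.selected
        assert again.val_f1 == fitted_model.val_f1

    def test_single_class_rejected(self, small_corpus):
        only_neg = [lm for lm in small_corpus if lm.gold_label == "non_cohesion"][:50]
        with pytest.raises(ValueError):
            gc.fit(only_neg)

    def test_too_few_examples_rejected(self, small_corpus):
        with pytest.raises(ValueError):
            gc.fit(small_corpus[:10])


class TestPredict:
    def test_empty_input_empty_output(self, fitted_model):
        assert gc.predict(fitted_model, []) == []

    def test_published_gratitude_fixture_scores_cohesion(self, fitted_model):
        # regression check of the end-to-end path, not ground truth
        out = gc.predict(
            fitted_model, [("m1", "Thank you everyone, this is such a great group.")]
        )
        assert out[0].vote_label == POSITIVE

    def test_order_preserved_and_deterministic(self, fitted_model, small_corpus):
        msgs = small_corpus[:30]
        a = gc.predict(fitted_model, msgs)
        b = gc.predict(fitted_model, msgs)
        assert a == b
        assert [s.message_id for s in a] == [lm.message.message_id for lm in msgs]

    def test_scores_within_unit_interval(self, fitted_model, small_corpus):
        for sm in gc.predict(fitted_model, small_corpus[:50]):
            assert 0.0 <= sm.raw_score <= 1.0
            assert 0.0 <= sm.confidence <= 1.0
            assert sum(v == sm.vote_label for v in sm.votes.values()) >= 2


def test_model_round_trip(tmp_path, fitted_model, small_corpus):
    fitted_model.save(tmp_path / "model")
    back = gc.EnsembleModel.load(tmp_path / "model")
    assert back.selected == fitted_model.selected
    assert back.val_f1 == fitted_model.val_f1
    assert gc.predict(back, small_corpus[:20]) == gc.predict(fitted_model, small_corpus[:20])
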