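"""Metrics, reports and the active-learning round."""

import pytest
from hypothesis import given, strategies as st
from sklearn.metrics import precision_recall_fscore_support

import groupcohesion as gc
from groupcohesion.evaluate import (
    ConfusionMatrix,
    EvalReport,
    active_learning_round,
    f1_from_pr,
    metrics,
    oracle_from_csv,
    render_table,
    stop_rule,
)

LABELS = ("cohesion", "non_cohesion")


class TestMetrics:
    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            metrics(ConfusionMatrix(0, 0, 0, 0))

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionMatrix(-1, 0, 0, 1)

    def test_perfect_classifier(self):
        p, r, f1 = metrics(ConfusionMatrix(tp=5, fp=0, fn=0, tn=5))
        assert (p, r, f1) == (1.0, 1.0, 1.0)

    def test_undefined_precision_is_none(self):
        p, r, f1 = metrics(ConfusionMatrix(tp=0, fp=0, fn=3, tn=7))
        assert p is None and r == 0.0 and f1 == 0.0

    @given(st.tuples(*[st.integers(0, 40)] * 4))
    def test_matches_independent_recount(self, counts):
        """Oracle: rebuild the per-example label pairs and let scikit-learn
        recompute precision/recall/F1."""
        tp, fp, fn, tn = counts
        if tp + fp + fn + tn == 0:
            return
        pred = ["cohesion"] * (tp + fp) + ["non_cohesion"] * (fn + tn)
        gold = (
            ["cohesion"] * tp + ["non_cohesion"] * fp
            + ["cohesion"] * fn + ["non_cohesion"] * tn
        )
        cm = ConfusionMatrix.from_pairs(pred, gold)
        assert (cm.tp, cm.fp, cm.fn, cm.tn) == (tp, fp, fn, tn)
        p, r, f1 = metrics(cm)
        sp, sr, sf, _ = precision_recall_fscore_support(
            gold, pred, pos_label="cohesion", average="binary", zero_division=0.0
        )
        if p is not None:
            assert p == pytest.approx(sp)
        if r is not None:
            assert r == pytest.approx(sr)
        assert f1 == pytest.approx(sf)

    @given(st.floats(0.01, 1), st.floats(0.01, 1))
    def test_f1_is_harmonic_mean_between_min_and_max(self, p, r):
        f1 = f1_from_pr(p, r)
        assert f1 == pytest.approx(2 * p * r / (p + r))
        assert min(p, r) - 1e-12 <= f1 <= max(p, r) + 1e-12


def _report(f1):
    return EvalReport(
        precision=1.0, recall=f1, f1=f1, counts=ConfusionMatrix(1, 0, 0, 0), round_id=1
    )


class TestStopRule:
    @pytest.mark.parametrize("f1,expect", [(0.82, True), (0.68, False), (0.80, True)])
    def test_threshold_inclusive(self, f1, expect):
        assert stop_rule(_report(f1)) is expect


def test_render_table_two_decimals():
    out = render_table([("First", _report(0.675)), ("Second", _report(0.8212))])
    assert "0.68" in out and "0.82" in out
    assert out.splitlines()[0].startswith("Scoring round/method")


def test_oracle_from_csv(tmp_path):
    path = tmp_path / "gold.csv"
    path.write_text("message_id,label\nm1,cohesion\nm2,non_cohesion\n")
    oracle = oracle_from_csv(path)
    assert oracle("m1") == "cohesion"
    with pytest.raises(KeyError):
        oracle("m3")


@pytest.fixture(scope="module")
def setup(small_corpus, cohesion_lexicon, fitted_model):
    train = small_corpus[:300]
    pool = small_corpus[300:]
    oracle = {lm.message.message_id: lm.gold_label for lm in small_corpus}
    return fitted_model, train, pool, oracle, cohesion_lexicon


class TestActiveLearningRound:
    def test_sample_size_every_fifth(self, setup):
        model, train, pool, oracle, lex = setup
        res = active_learning_round(
            model, train, pool[:250], oracle.__getitem__, lex, k=5, seed=1
        )
        assert res.report.counts.total == 50

    def test_self_oracle_perfect_matrix_lexicon_unchanged(self, setup, small_corpus):
        model, train, pool, _, lex = setup
        sample = gc.sample_every_kth(pool, 5)
        scored = gc.predict(model, sample)
        adjusted = gc.apply_rules(scored, [lm.message.text for lm in sample])
        self_labels = {a.message_id: a.final_label for a in adjusted}
        res = active_learning_round(
            model, train, pool, self_labels.__getitem__, lex, k=5, seed=1
        )
        assert res.report.counts.fp == 0 and res.report.counts.fn == 0
        assert res.report.f1 in (1.0, 0.0)  # 0.0 only if no positives at all
        assert res.lexicon.human_added == lex.human_added

    def test_missing_oracle_id_named(self, setup):
        model, train, pool, oracle, lex = setup
        broken = dict(oracle)
        victim = pool[0].message.message_id
        del broken[victim]
        with pytest.raises(ValueError, match=victim):
            active_learning_round(
                model, train, pool, broken.__getitem__, lex, k=5, seed=1
            )

    def test_lexicon_never_shrinks_and_errors_grouped_by_theme(self, setup):
        model, train, pool, oracle, lex = setup
        res = active_learning_round(
            model, train, pool, oracle.__getitem__, lex, k=5, seed=1
        )
        assert len(res.lexicon) >= len(lex)
        for theme, ids in res.report.false_negatives.items():
            assert isinstance(theme, str) and ids
        assert len(res.train) == len(train) + res.report.counts.total
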