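"""Generator contracts: label rates, trap structure, determinism, round trip."""

import math

import pytest

import groupcohesion as gc
from groupcohesion.synthetic_corpus import (
    COHESION_THEMES,
    TRAP_LABELS,
    from_record,
    read_jsonl,
    template_bank,
    to_record,
    write_jsonl,
)


def _cohesion_fraction(corpus):
    return sum(lm.gold_label == "cohesion" for lm in corpus) / len(corpus)


class TestGenConfig:
    @pytest.mark.parametrize(
        "kwargs,fieldname",
        [
            (dict(cohesion_rate=1.2), "cohesion_rate"),
            (dict(trap_rate=-0.1), "trap_rate"),
            (dict(cohesion_rate=0.7, trap_rate=0.5), "trap_rate"),
            (dict(n_sessions=0), "n_sessions"),
            (dict(messages_per_session=0), "messages_per_session"),
            (dict(session_duration=0), "session_duration"),
        ],
    )
    def test_invalid_rejected_naming_field(self, kwargs, fieldname):
        with pytest.raises(ValueError, match=fieldname.split("_")[0]):
            gc.GenConfig(**kwargs)


class TestGenerateCorpus:
    def test_size_and_approximate_rate(self):
        cfg = gc.GenConfig(
            n_sessions=1, messages_per_session=100, cohesion_rate=0.3, seed=1
        )
        corpus = gc.generate_corpus(cfg)
        assert len(corpus) == 100
        p, n = 0.3, 100
        tol = 3 * math.sqrt(p * (1 - p) / n)
        assert abs(_cohesion_fraction(corpus) - p) <= tol

    def test_zero_rate_yields_no_cohesion(self):
        cfg = gc.GenConfig(n_sessions=1, messages_per_session=200, cohesion_rate=0.0, seed=2)
        assert _cohesion_fraction(gc.generate_corpus(cfg)) == 0.0

    def test_deterministic_byte_identical_jsonl(self, tmp_path):
        cfg = gc.GenConfig(n_sessions=2, messages_per_session=50, seed=5)
        for name in ("a", "b"):
            write_jsonl(gc.generate_corpus(cfg), tmp_path / f"{name}.jsonl")
        assert (tmp_path / "a.jsonl").read_bytes() == (tmp_path / "b.jsonl").read_bytes()

    def test_theme_coverage_at_n500(self):
        cfg = gc.GenConfig(
            n_sessions=5, messages_per_session=100, cohesion_rate=0.3, trap_rate=0.15, seed=3
        )
        themes = {lm.theme for lm in gc.generate_corpus(cfg)}
        assert set(COHESION_THEMES) <= themes
        assert len(themes & set(TRAP_LABELS)) >= 4

    def test_timestamps_sorted_within_session(self, small_corpus):
        by_session = {}
        for lm in small_corpus:
            by_session.setdefault(lm.message.session_id, []).append(lm.message.timestamp)
        for ts in by_session.values():
            assert ts == sorted(ts)
            assert all(0 <= t <= 90 * 60 for t in ts)

    def test_trap_labels_consistent(self, small_corpus):
        for lm in small_corpus:
            if lm.theme in TRAP_LABELS:
                assert lm.gold_label == TRAP_LABELS[lm.theme]

    def test_label_balance_converges(self):
        # binomial tolerance shrinks with n; check at two sizes
        for n_sessions, tol_scale in ((2, 1.0), (8, 0.5)):
            cfg = gc.GenConfig(
                n_sessions=n_sessions, messages_per_session=250, cohesion_rate=0.2, seed=13
            )
            corpus = gc.generate_corpus(cfg)
            n = len(corpus)
            tol = 3 * math.sqrt(0.2 * 0.8 / n)
            assert abs(_cohesion_fraction(corpus) - 0.2) <= tol


class TestTemplateBank:
    def test_published_fixture_strings_present(self):
        bank = template_bank()
        assert "Thank you everyone, this is such a great group." in bank["gratitude"]
        assert "sending hugs" in bank["support"]
        assert "thanks everyone for your support <3" in bank["support"]
        assert "I am glad to be part of this group" in bank["belonging"]
        assert "we are friends" in bank["shared_experience"]
        # outside-group support trap mentions family/friend support
        joined = " ".join(bank["trap_outside_support"]).lower()
        assert any(w in joined for w in ("husband", "children", "sister", "friends"))

    def test_templates_render_nonempty_for_all_fillings(self):
        import numpy as np

        rng = np.random.default_rng(0)
        for templates in template_bank().values():
            for t in templates:
                for _ in range(6):
                    assert gc.synthetic_corpus.render(t, rng).strip()

    def test_keyword_we_is_not_linearly_separating(self):
        """At least one gold non-cohesion trap contains 'we'; at least one
        cohesion template has none of we/us/our."""
        bank = template_bank()
        noncoh_trap_texts = bank["trap_negated_cohesion"] + bank["trap_outside_support"]
        assert any(" we " in f" {t.lower()} " for t in noncoh_trap_texts)
        cohesion_texts = [t for th in COHESION_THEMES for t in bank[th]] + bank[
            "trap_empathy_no_we"
        ]
        def has_group_pronoun(t):
            toks = set(t.lower().replace(",", " ").replace(".", " ").split())
            return toks & {"we", "us", "our"}
        assert any(not has_group_pronoun(t) for t in cohesion_texts)


def test_jsonl_round_trip_field_by_field(tmp_path, small_corpus):
    path = tmp_path / "c.jsonl"
    write_jsonl(small_corpus[:100], path)
    back = read_jsonl(path)
    assert back == list(small_corpus[:100])


def test_record_round_trip():
    lm = gc.generate_corpus(gc.GenConfig(n_sessions=1, messages_per_session=1, seed=0))[0]
    assert from_record(to_record(lm)) == lm
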