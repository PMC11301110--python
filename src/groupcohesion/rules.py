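"""Rule-based adjustment of per-message cohesion scores.

Five hand-coded linguistic rules fine-tune the ensemble's probability before
the final label is taken, applied in a fixed order:

1. negation — a negation cue anywhere in the message zeroes the score
   outright (short-circuit; no later rule can resurrect it);
2. past tense — the score is halved: an event already in the past is
   assumed to weigh less on the writer's present state;
3. empathy — an empathy cue phrase doubles the score to reflect intensity;
4. intensifiers — each booster adverb multiplies the score by a per-booster
   factor (default 1.25), with at most two boosters counted;
5. person — when second/third-person pronouns suppress the first-person
   flag, the event is recorded; the default multiplier is 1.0 (flag-only).

The result is clamped to [0, 1] and thresholded at 0.5 for the final label.
Because every rule after negation is multiplicative with a positive factor
and the clamp is monotone, the adjusted score is monotone in the raw score
for fixed flags.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from .classifier import NEGATIVE, POSITIVE, ScoredMessage
from .preprocess import LinguisticFlags, analyze, load_wordlist, tokenize


@dataclass(frozen=True)
class RuleConfig:
    past_tense_multiplier: float = 0.5
    empathy_multiplier: float = 2.0
    intensifier_multiplier: float = 1.25  # per booster
    intensifier_cap: int = 2  # max boosters counted
    second_third_person_multiplier: float = 1.0
    final_threshold: float = 0.5

    def __post_init__(self) -> None:
        for name in (
            "past_tense_multiplier",
            "empathy_multiplier",
            "intensifier_multiplier",
            "second_third_person_multiplier",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not 0.0 < self.final_threshold < 1.0:
            raise ValueError("final_threshold must be in (0,1)")
        if self.intensifier_cap < 0:
            raise ValueError("intensifier_cap must be >= 0")


@dataclass(frozen=True)
class AdjustedScore:
    message_id: str
    raw_score: float
    adjusted_score: float
    fired_rules: tuple[str, ...]
    final_label: str


# ---------------------------------------------------------------------------
# empathy cues

_DEFAULT_EMPATHY: tuple[str, ...] | None = None


def empathy_lexicon(path: str | Path | None = None) -> tuple[str, ...]:
    """Empathy cue phrases (packaged default, or a user-supplied file)."""
    global _DEFAULT_EMPATHY
    if path is not None:
        return tuple(load_wordlist(path))
    if _DEFAULT_EMPATHY is None:
        _DEFAULT_EMPATHY = tuple(load_wordlist("empathy.txt"))
    return _DEFAULT_EMPATHY


def detect_empathy(text: str, lexicon: Sequence[str] | None = None) -> bool:
    """True iff any cue phrase occurs in the tokenized message.

    Matching is case-insensitive over the token stream, so punctuation and
    contraction spelling do not break a match.
    """
    if not text or not text.strip():
        raise ValueError("detect_empathy() requires non-empty text")
    cues = tuple(lexicon) if lexicon is not None else empathy_lexicon()
    joined = " " + " ".join(tokenize(text)) + " "
    for cue in cues:
        cue_joined = " " + " ".join(tokenize(cue)) + " "
        if cue_joined in joined:
            return True
    return False


# ---------------------------------------------------------------------------
# adjustment

def adjust(
    raw_score: float,
    flags: LinguisticFlags,
    empathy_hit: bool,
    config: RuleConfig = RuleConfig(),
    message_id: str = "",
) -> AdjustedScore:
    """Apply the rule cascade to one message's raw ensemble score."""
    if not 0.0 <= raw_score <= 1.0:
        raise ValueError(f"raw_score out of [0,1]: {raw_score}")
    fired: list[str] = []

    if flags.has_negation:
        return AdjustedScore(
            message_id=message_id,
            raw_score=raw_score,
            adjusted_score=0.0,
            fired_rules=("negation",),
            final_label=NEGATIVE,
        )

    score = raw_score
    if flags.has_past_tense:
        score *= config.past_tense_multiplier
        fired.append("past_tense")
    if empathy_hit:
        score *= config.empathy_multiplier
        fired.append("empathy")
    if flags.intensifier_count > 0:
        n = min(flags.intensifier_count, config.intensifier_cap)
        score *= config.intensifier_multiplier**n
        fired.append("intensifier")
    if not flags.first_person:
        score *= config.second_third_person_multiplier
        fired.append("person")
    score = min(1.0, max(0.0, score))

    return AdjustedScore(
        message_id=message_id,
        raw_score=raw_score,
        adjusted_score=score,
        fired_rules=tuple(fired),
        final_label=POSITIVE if score >= config.final_threshold else NEGATIVE,
    )


def apply_rules(
    scored: Sequence[ScoredMessage],
    texts: Sequence[str],
    config: RuleConfig = RuleConfig(),
    empathy_cues: Sequence[str] | None = None,
) -> list[AdjustedScore]:
    """Run the cascade over ensemble outputs paired with their texts."""
    if len(scored) != len(texts):
        raise ValueError("scored and texts must be the same length")
    out = []
    for sm, text in zip(scored, texts):
        flags = analyze(text)
        out.append(
            adjust(
                sm.raw_score,
                flags,
                detect_empathy(text, empathy_cues),
                config,
                message_id=sm.message_id,
            )
        )
    return out
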