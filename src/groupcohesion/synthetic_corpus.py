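"""Synthetic labeled transcripts of online support group (OSG) chat sessions.

Real OSG chat corpora are clinical data and cannot be redistributed, so the
pipeline is exercised on generated transcripts that reproduce the structure
the method assumes: 90-minute sessions of short messages from a handful of
participants plus a facilitator, a minority of messages expressing group
cohesion across eight recurring themes (reassurance, support, emotional
disclosure and trust, belonging, gratitude, shared experience, positive
reflection, anticipating future sessions), and a controlled fraction of
"trap" messages that defeat naive keyword matching:

* negated or hurt-context uses of "we"/"us" (gold non-cohesion),
* support from family or friends outside the group (gold non-cohesion,
  deliberately containing first-person-plural language),
* idioms expressing togetherness (gold cohesion, no obvious keyword),
* empathy statements without any "we"-language (gold cohesion).

Templates are hand-written slot-filling strings (intensifier, tense and
negation variants); there is no neural generation, so every message's gold
label is exact by construction. A single integer seed drives one
``numpy.random.Generator`` and makes output byte-identical across runs.
"""

from __future__ import annotations

import csv
import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

SESSION_MINUTES_DEFAULT = 90

COHESION_THEMES = (
    "reassurance",
    "support",
    "disclosure_trust",
    "belonging",
    "gratitude",
    "shared_experience",
    "positive_reflection",
    "future_anticipation",
)

#: trap category -> gold label carried by its templates
TRAP_LABELS = {
    "trap_negated_cohesion": "non_cohesion",
    "trap_outside_support": "non_cohesion",
    "trap_idiom": "cohesion",
    "trap_empathy_no_we": "cohesion",
}

NEUTRAL_THEME = "neutral"


# ---------------------------------------------------------------------------
# configuration

@dataclass(frozen=True)
class GenConfig:
    """Corpus generator settings.

    ``cohesion_rate`` is the marginal probability that a message's gold label
    is cohesion; ``trap_rate`` is the probability that a message (of either
    label) is drawn from a trap template bank instead of a plain one.
    """

    n_sessions: int = 10
    messages_per_session: int = 200
    cohesion_rate: float = 0.2
    trap_rate: float = 0.1
    session_duration: float = SESSION_MINUTES_DEFAULT
    n_participants: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_sessions", "messages_per_session", "n_participants"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1, got {getattr(self, name)}")
        for name in ("cohesion_rate", "trap_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability in [0,1], got {v}")
        if self.cohesion_rate + self.trap_rate > 1.0:
            raise ValueError(
                "cohesion_rate + trap_rate must be <= 1, got "
                f"{self.cohesion_rate} + {self.trap_rate}"
            )
        if self.session_duration <= 0:
            raise ValueError(f"session_duration must be > 0, got {self.session_duration}")


@dataclass(frozen=True)
class Message:
    session_id: str
    message_id: str
    participant_id: str
    timestamp: float  # seconds from session start
    text: str
    role: str  # "participant" | "therapist"


@dataclass(frozen=True)
class LabeledMessage:
    message: Message
    gold_label: str  # "cohesion" | "non_cohesion"
    theme: str | None = None


# ---------------------------------------------------------------------------
# template bank

_INTENSIFIERS = ("", "so much ", "very ", "really ")


def _v(*variants: str) -> list[str]:
    return list(variants)


def template_bank() -> dict[str, list[str]]:
    """Theme -> text templates, including the published example fixtures.

    Templates may carry a ``{i}`` slot filled with an intensifier ("",
    "so much ", "very ", "really "). Tense and negation variants are written
    out as separate templates so each string's gold label stays exact.
    """
    return {
        "reassurance": _v(
            "Good for you, that must have been really difficult to do",
            "You handled that {i}well, keep going",
            "You are doing great, one day at a time",
            "Good for you, that takes {i}courage",
        ),
        "support": _v(
            "sending hugs",
            "thanks everyone for your support <3",
            "I feel {i}supported by this group",
            "thank you for your support and input",
            "We are here for each other",
        ),
        "disclosure_trust": _v(
            "At my last treatment, I felt really scared, I didn't want to tell"
            " my family this. But I can tell this group",
            "I can share things here that I can't say anywhere else",
            "I trust this group {i}completely with my story",
            "It feels safe to open up here",
        ),
        "belonging": _v(
            "I am glad to be part of this group",
            "I'm so glad I found this group",
            "I {i}feel like I belong here",
            "Being part of this group means a lot to me",
        ),
        "gratitude": _v(
            "Thank you everyone, this is such a great group.",
            "Thank you all {i}for listening tonight",
            "I am {i}grateful for this group",
            "thanks to all of you for being in this moment",
        ),
        "shared_experience": _v(
            "It is amazing how much we all have in common",
            "we are friends",
            "We have all been through the same thing",
            "So many of us share this experience",
        ),
        "positive_reflection": _v(
            "This group has been a great resource venue for meeting and I will"
            " continue down the road with fond memories of the time spent here",
            "A very good chat session",
            "time went by fast!",
            "I am going to miss this group",
        ),
        "future_anticipation": _v(
            "I can't wait to chat with you all next week",
            "Looking forward to our next session",
            "See you all next time, I will be counting the days",
            "thinking of you all!",
        ),
        # traps ------------------------------------------------------------
        "trap_negated_cohesion": _v(
            "When I mentioned that last week, when we all said what our"
            " situations were, no one even acknowledged it. I was very hurt"
            " by that",
            "I do not feel supported by this group at all",
            "We never seem to listen to each other in here",
            "Nobody in our group understood what I meant",
        ),
        "trap_outside_support": _v(
            "When I put my things in order I involved my children and as"
            " challenging and emotional as it was it made it easier for me and"
            " for them - we laughed and cried but it really made me feel"
            " supported",
            "My husband has been {i}supportive at home, we get through it"
            " together",
            "My sister and I talk every day, she keeps me going",
            "My friends from work sent me {i}lovely flowers",
        ),
        "trap_idiom": _v(
            "been there, am there... got the t-shirt",
            "we are joining our circle",
            "I hope you don't think you've been placed in a hot seat. It's"
            " just that I missed you and worried about you.",
            "same boat, different paddle, all of us rowing along",
        ),
        "trap_empathy_no_we": _v(
            "I can relate",
            "I feel the same way",
            "I am with you, be strong please",
            "I am sure there will be a sense of connection, so much sharing"
            " already",
            "I am sure I will think of you often",
            "Are you going to be alright? I want you to know how much I"
            " appreciate your presence.",
        ),
        # plain non-cohesion filler ----------------------------------------
        "neutral": _v(
            "My appointment got moved to Thursday morning",
            "The side effects were {i}rough this week",
            "Does anyone know how long the fatigue lasts?",
            "I read the homework chapter on the bus",
            "The nurse said to drink more water",
            "My scan is scheduled for next month",
            "I had trouble sleeping again last night",
            "What page was the reading on?",
            "The weather is nice today",
            "I tried a new recipe for dinner",
        ),
        "facilitation": _v(
            "Let's move to the next question from the reading",
            "Would anyone like to respond to that?",
            "Take your time, there is no rush tonight",
            "That is an important point, thank you for raising it",
        ),
    }


def render(template: str, rng: np.random.Generator) -> str:
    """Fill the intensifier slot; always yields non-empty text."""
    if "{i}" in template:
        template = template.replace("{i}", str(rng.choice(_INTENSIFIERS)))
    return template


# ---------------------------------------------------------------------------
# generation

def generate_corpus(config: GenConfig) -> list[LabeledMessage]:
    """Generate labeled session transcripts.

    The gold label is drawn first (Bernoulli ``cohesion_rate``), then with
    probability ``trap_rate`` the text comes from a trap bank whose gold
    label matches; this keeps the empirical cohesion fraction binomial
    around ``cohesion_rate`` while planting traps on both sides of the
    label. Timestamps are uniform order statistics over the session, so
    they are non-decreasing by construction. Every 10th post is the
    facilitator's.
    """
    rng = np.random.default_rng(config.seed)
    bank = template_bank()
    cohesion_traps = [t for t, lab in TRAP_LABELS.items() if lab == "cohesion"]
    noncoh_traps = [t for t, lab in TRAP_LABELS.items() if lab == "non_cohesion"]
    duration_s = config.session_duration * 60.0

    out: list[LabeledMessage] = []
    for s in range(config.n_sessions):
        session_id = f"S{s:03d}"
        n = config.messages_per_session
        times = np.sort(rng.uniform(0.0, duration_s, size=n))
        for j in range(n):
            is_therapist = (j % 10) == 9
            participant_id = (
                "therapist"
                if is_therapist
                else f"P{int(rng.integers(config.n_participants)):02d}"
            )
            is_cohesion = rng.random() < config.cohesion_rate
            is_trap = rng.random() < config.trap_rate
            if is_cohesion:
                theme = str(
                    rng.choice(cohesion_traps if is_trap else COHESION_THEMES)
                )
                gold = "cohesion"
            elif is_trap:
                theme = str(rng.choice(noncoh_traps))
                gold = "non_cohesion"
            elif is_therapist:
                theme, gold = "facilitation", "non_cohesion"
            else:
                theme, gold = NEUTRAL_THEME, "non_cohesion"
            text = render(str(rng.choice(bank[theme])), rng)
            msg = Message(
                session_id=session_id,
                message_id=f"{session_id}-M{j:04d}",
                participant_id=participant_id,
                timestamp=round(float(times[j]), 3),
                text=text,
                role="therapist" if is_therapist else "participant",
            )
            out.append(LabeledMessage(message=msg, gold_label=gold, theme=theme))
    return out


# ---------------------------------------------------------------------------
# serialization: JSONL transcript + companion labels CSV

def to_record(lm: LabeledMessage) -> dict:
    rec = asdict(lm.message)
    rec["gold_label"] = lm.gold_label
    rec["theme"] = lm.theme
    return rec


def from_record(rec: dict) -> LabeledMessage:
    gold = rec.pop("gold_label")
    theme = rec.pop("theme", None)
    return LabeledMessage(message=Message(**rec), gold_label=gold, theme=theme)


def write_jsonl(corpus: Sequence[LabeledMessage], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for lm in corpus:
            fh.write(json.dumps(to_record(lm), ensure_ascii=False) + "\n")


def read_jsonl(path: str | Path) -> list[LabeledMessage]:
    out = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if line.strip():
                out.append(from_record(json.loads(line)))
    return out


def write_labels_csv(corpus: Sequence[LabeledMessage], path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["message_id", "gold_label", "theme"])
        for lm in corpus:
            w.writerow([lm.message.message_id, lm.gold_label, lm.theme or ""])
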