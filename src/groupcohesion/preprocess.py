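"""Tokenization and message-level linguistic flags.

Everything downstream of the classifier (the rule layer, the dictionary
baseline, empathy detection) consumes the output of :func:`analyze`, so the
tokenizer is deliberately rule-based and closed: lowercasing, clitic
splitting (``didn't`` -> ``did`` + ``n't``), punctuation as separate tokens,
emoticons (``<3``, ``:)``) passed through untouched. Part-of-speech tagging
is a coarse lexicon-driven layer whose only load-bearing output is the
past-tense flag; it uses closed-class lookups, an irregular-past verb list
and an ``-ed`` suffix rule.

All word lists ship as plain-text package data (one term per line, ``#``
comments allowed) and can be overridden with a file path; nothing is
downloaded at run time.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence, TypeVar

_T = TypeVar("_T")

# ---------------------------------------------------------------------------
# packaged word lists

_DATA_PACKAGE = "groupcohesion.data"


def load_wordlist(name_or_path: str | Path) -> list[str]:
    """Read a one-term-per-line lexicon, skipping blanks and ``#`` comments.

    ``name_or_path`` is either a filename inside the package data directory
    (e.g. ``"negation.txt"``) or a path to a user-supplied override file.
    """
    p = Path(name_or_path)
    if p.exists():
        text = p.read_text(encoding="utf-8")
    else:
        text = (resources.files(_DATA_PACKAGE) / str(name_or_path)).read_text(
            encoding="utf-8"
        )
    terms = []
    for line in text.splitlines():
        line = line.strip().lower()
        if line and not line.startswith("#"):
            terms.append(line)
    return terms


NEGATION_WORDS = frozenset(load_wordlist("negation.txt"))
BOOSTERS = tuple(load_wordlist("boosters.txt"))
PRONOUNS = {
    "first_singular": frozenset(load_wordlist("pronouns_first_singular.txt")),
    "first_plural": frozenset(load_wordlist("pronouns_first_plural.txt")),
    "second": frozenset(load_wordlist("pronouns_second.txt")),
    "third": frozenset(load_wordlist("pronouns_third.txt")),
}

# ---------------------------------------------------------------------------
# tokenizer

# emoticons first so "<3" survives as one token; then words with internal
# apostrophes; then any single non-space symbol as punctuation
_EMOTICON = r"(?:<3|:\)|:\(|:d|:p|;\)|:-\)|:-\()"
_WORD = r"[a-z0-9]+(?:'[a-z]+)*"
_TOKEN_RE = re.compile(rf"{_EMOTICON}|{_WORD}|[^\sa-z0-9]", re.IGNORECASE)

# clitics split off the host word; "n't" is kept distinct for negation
_CLITIC_RE = re.compile(r"^([a-z]+)(n't|'s|'m|'re|'ve|'ll|'d)$")


def tokenize(text: str) -> list[str]:
    """Lowercase rule-based word tokenizer with clitic splitting."""
    tokens: list[str] = []
    for raw in _TOKEN_RE.findall(text.lower()):
        m = _CLITIC_RE.match(raw)
        if m:
            tokens.extend(m.groups())
        else:
            tokens.append(raw)
    return tokens


# ---------------------------------------------------------------------------
# coarse part-of-speech layer

_IRREGULAR_PAST = frozenset(
    """
    was were had did said went got made came took saw knew thought told felt
    found gave left kept began brought held wrote stood heard let meant met
    ran paid sat spoke lost sent built fell understood drew broke spent grew
    drove bought wore chose ate slept threw woke cried laughed been done gone
    seen known taken given written spoken broken chosen eaten fallen gotten
    """.split()
)

# -ed words that are not past verbs (or are far more often adjectives/nouns)
_ED_EXCEPTIONS = frozenset(
    "bed red wed fed led bred shed sled need indeed speed feed seed naked "
    "sacred hundred kindred wicked hatred".split()
)

_DETERMINERS = frozenset("a an the this that these those".split())
_BE_PRESENT = frozenset("am is are be being".split())
_ALL_PRONOUNS = frozenset().union(*PRONOUNS.values())


def _tag(token: str) -> str:
    if token in _ALL_PRONOUNS:
        return "PRON"
    if token in _DETERMINERS:
        return "DET"
    if token in _BE_PRESENT:
        return "VERB"
    if token in _IRREGULAR_PAST:
        return "VERB_PAST"
    if (
        len(token) > 3
        and token.endswith("ed")
        and token not in _ED_EXCEPTIONS
        and token.isalpha()
    ):
        return "VERB_PAST"
    if not token[:1].isalnum() and token not in ("<3",):
        return "PUNCT"
    return "X"


def pos_tags(tokens: Sequence[str]) -> list[str]:
    """Coarse tags aligned 1:1 with ``tokens``.

    ``VERB_PAST`` covers both simple-past and past-participle forms; the
    distinction does not matter for the half-score rule downstream.
    """
    return [_tag(t) for t in tokens]


# ---------------------------------------------------------------------------
# flags

@dataclass(frozen=True)
class LinguisticFlags:
    """Message-level linguistic features feeding the rule layer."""

    tokens: tuple[str, ...]
    pos_tags: tuple[str, ...]
    has_past_tense: bool
    has_negation: bool
    person: frozenset[str]
    first_person: bool
    intensifier_count: int
    is_question: bool


def _count_boosters(tokens: Sequence[str]) -> int:
    """Greedy longest-match count of booster phrases over the token stream."""
    phrases = sorted((tuple(b.split()) for b in BOOSTERS), key=len, reverse=True)
    count = 0
    i = 0
    n = len(tokens)
    while i < n:
        for ph in phrases:
            if tuple(tokens[i : i + len(ph)]) == ph:
                count += 1
                i += len(ph)
                break
        else:
            i += 1
    return count


def analyze(text: str) -> LinguisticFlags:
    """Derive :class:`LinguisticFlags` for one message.

    Raises ``ValueError`` on empty/whitespace-only text. Negation and person
    are message-global flags: no scope resolution is attempted.
    """
    if not text or not text.strip():
        raise ValueError("analyze() requires non-empty text")
    tokens = tokenize(text)
    tags = pos_tags(tokens)
    tokset = set(tokens)
    person = frozenset(
        name for name, words in PRONOUNS.items() if tokset & words
    )
    # first-person flag flips to False as soon as a second- or third-person
    # pronoun appears anywhere in the message
    first_person = bool(
        person & {"first_singular", "first_plural"}
    ) and not bool(person & {"second", "third"})
    return LinguisticFlags(
        tokens=tuple(tokens),
        pos_tags=tuple(tags),
        has_past_tense="VERB_PAST" in tags,
        has_negation=bool(tokset & NEGATION_WORDS),
        person=person,
        first_person=first_person,
        intensifier_count=_count_boosters(tokens),
        is_question="?" in tokens,
    )


# ---------------------------------------------------------------------------
# systematic sampling

def sample_every_kth(messages: Sequence[_T] | Iterable[_T], k: int) -> list[_T]:
    """Messages at positions 0, k, 2k, ... in transcript order.

    The result has ``ceil(n / k)`` elements. ``k`` below 1 is rejected.
    """
    if k < 1:
        raise ValueError(f"sampling stride k must be >= 1, got {k}")
    seq = list(messages)
    out = seq[::k]
    assert len(out) == math.ceil(len(seq) / k)
    return out
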