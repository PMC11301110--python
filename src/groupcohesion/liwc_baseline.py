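"""Dictionary-category baseline for cohesion detection.

The comparison method counts, for each of five word categories — "we",
"positive_emotion", "family", "friend", "affiliation" — the percentage of a
message's words matching that category, and calls the message cohesion when
at least 3 of the 5 categories are met (any match, i.e. percentage > 0).

The proprietary LIWC dictionaries cannot be shipped; the package bundles
small open stand-in lists in the same ``.dic``-style format (``%CAT name``
header, one lowercase pattern per line, trailing ``*`` = prefix wildcard)
and accepts user-supplied dictionaries in that format. Tokenization is
shared with the rest of the pipeline so counts are comparable.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping

from .preprocess import tokenize

REQUIRED_CATEGORIES = ("we", "positive_emotion", "family", "friend", "affiliation")
CRITERION = 3  # categories that must be met

_STANDIN_RESOURCE = "categories_standin.dic"


@dataclass(frozen=True)
class CategoryDictionary:
    name: str
    exact: frozenset[str]
    prefixes: tuple[str, ...]

    def matches(self, token: str) -> bool:
        return token in self.exact or any(
            token.startswith(p) for p in self.prefixes
        )


@dataclass(frozen=True)
class CategoryProfile:
    percentages: dict[str, float]  # category -> % of tokens matching
    met: dict[str, bool]
    label: str  # "cohesion" | "non_cohesion"


def _parse(text: str, source: str) -> dict[str, CategoryDictionary]:
    cats: dict[str, tuple[set[str], list[str]]] = {}
    current: str | None = None
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if line.startswith("%"):
            parts = line.split()
            if len(parts) != 2 or parts[0] != "%CAT":
                raise ValueError(
                    f"{source}:{lineno}: malformed category header {line!r}"
                    " (expected '%CAT <name>')"
                )
            current = parts[1].lower()
            cats.setdefault(current, (set(), []))
            continue
        if current is None:
            raise ValueError(
                f"{source}:{lineno}: pattern {line!r} before any '%CAT' header"
            )
        pat = line.lower()
        exact, prefixes = cats[current]
        if pat.endswith("*"):
            prefixes.append(pat[:-1])
        else:
            exact.add(pat)
    missing = [c for c in REQUIRED_CATEGORIES if c not in cats or not any(cats[c])]
    if missing:
        raise ValueError(
            f"{source}: missing or empty required categories: {', '.join(missing)}"
        )
    return {
        name: CategoryDictionary(
            name=name, exact=frozenset(exact), prefixes=tuple(prefixes)
        )
        for name, (exact, prefixes) in cats.items()
    }


def load_dictionary(path: str | Path) -> dict[str, CategoryDictionary]:
    """Parse a ``.dic``-style file; all five categories must be present."""
    p = Path(path)
    return _parse(p.read_text(encoding="utf-8"), source=str(p))


def default_dictionaries() -> dict[str, CategoryDictionary]:
    """The bundled open stand-in dictionaries (not LIWC)."""
    text = (
        resources.files("groupcohesion.data") / _STANDIN_RESOURCE
    ).read_text(encoding="utf-8")
    return _parse(text, source=_STANDIN_RESOURCE)


def classify_baseline(
    text: str, dictionaries: Mapping[str, CategoryDictionary] | None = None
) -> CategoryProfile:
    """Category percentages and the 3-of-5 label for one message.

    Word tokens only enter the denominator (punctuation is excluded); a
    token may count toward several categories.
    """
    if not text or not text.strip():
        raise ValueError("classify_baseline() requires non-empty text")
    dicts = dictionaries if dictionaries is not None else default_dictionaries()
    words = [t for t in tokenize(text) if any(ch.isalnum() for ch in t)]
    n = len(words)
    percentages: dict[str, float] = {}
    met: dict[str, bool] = {}
    for name in REQUIRED_CATEGORIES:
        d = dicts[name]
        hits = sum(1 for w in words if d.matches(w)) if n else 0
        pct = 100.0 * hits / n if n else 0.0
        percentages[name] = pct
        met[name] = pct > 0.0
    label = "cohesion" if sum(met.values()) >= CRITERION else "non_cohesion"
    return CategoryProfile(percentages=percentages, met=met, label=label)
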