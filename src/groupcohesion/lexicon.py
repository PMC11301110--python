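"""Corpus-trained word embeddings and cohesion-lexicon expansion.

Annotated seed expressions ("us", "we", "our group", plus one seed list per
cohesion theme) are expanded into a larger set of contextually similar
expressions by querying nearest neighbors in an embedding space trained on
the working corpus itself (no pretrained vectors).

The embedding estimator is count-based: a symmetric windowed co-occurrence
matrix over the vocabulary (window 10, minimum term frequency 2), positive
pointwise mutual information (PPMI) weighting, then a truncated SVD with the
word vectors taken as ``U * sqrt(S)``. This factorization is the classical
closed-form counterpart of skip-gram training and, unlike stochastic
gradient training, is exactly reproducible and well behaved on the small
corpora this package targets. Sign indeterminacy of the SVD is fixed by
orienting each component so its largest-magnitude loading is positive.
"""

from __future__ import annotations

import json
import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import scipy.sparse as sp

logger = logging.getLogger(__name__)

DEFAULT_TOP_K = 10
DEFAULT_MIN_SIMILARITY = 0.5


@dataclass(frozen=True)
class EmbeddingConfig:
    """Hyperparameters of the co-occurrence embedding.

    dimension: length of every word vector (default 100).
    window: symmetric context window in tokens (default 10).
    min_count: minimum corpus frequency for a term to get a vector (default 2).
    seed: kept for interface stability; the estimator is deterministic.
    """

    dimension: int = 100
    window: int = 10
    min_count: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("dimension", "window", "min_count"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1, got {getattr(self, name)}")


class EmbeddingModel:
    """Term -> vector mapping with cosine-similarity queries."""

    def __init__(self, vocab: Sequence[str], vectors: np.ndarray, config: EmbeddingConfig):
        self.vocab = list(vocab)
        self.index = {t: i for i, t in enumerate(self.vocab)}
        self.vectors = np.asarray(vectors, dtype=np.float64)
        self.config = config
        norms = np.linalg.norm(self.vectors, axis=1, keepdims=True)
        norms[norms == 0] = 1.0
        self._unit = self.vectors / norms

    def __contains__(self, term: str) -> bool:
        return term in self.index

    def vector(self, expression: str) -> np.ndarray | None:
        """Vector for a term, or the mean of in-vocabulary tokens of a
        multi-word expression; None if nothing is in vocabulary."""
        toks = expression.lower().split()
        rows = [self.index[t] for t in toks if t in self.index]
        if not rows:
            return None
        return self.vectors[rows].mean(axis=0)

    def similarity(self, a: str, b: str) -> float:
        va, vb = self.vector(a), self.vector(b)
        if va is None or vb is None:
            raise KeyError(f"expression not in vocabulary: {a if va is None else b}")
        return _cosine(va, vb)

    def most_similar(
        self, expression: str, top_k: int = DEFAULT_TOP_K, exclude: set[str] | None = None
    ) -> list[tuple[str, float]]:
        if top_k <= 0:
            return []
        v = self.vector(expression)
        if v is None:
            return []
        nv = np.linalg.norm(v)
        if nv == 0:
            return []
        sims = self._unit @ (v / nv)
        exclude = (exclude or set()) | set(expression.lower().split())
        order = np.argsort(-sims)
        out = []
        for i in order:
            term = self.vocab[i]
            if term in exclude:
                continue
            out.append((term, float(sims[i])))
            if len(out) >= top_k:
                break
        return out


def _cosine(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    return float(a @ b / (na * nb))


def train_embeddings(
    corpus: Iterable[Sequence[str]], config: EmbeddingConfig = EmbeddingConfig()
) -> EmbeddingModel:
    """Fit the PPMI-SVD embedding on tokenized messages.

    Every term with corpus frequency >= ``min_count`` receives a vector of
    length ``dimension`` (zero-padded when the vocabulary is smaller than the
    requested rank). Raises ``ValueError`` if fewer than two distinct terms
    survive the frequency filter.
    """
    sentences = [list(s) for s in corpus]
    freq = Counter(t for s in sentences for t in s)
    vocab = sorted(t for t, c in freq.items() if c >= config.min_count)
    if len(vocab) < 2:
        raise ValueError(
            "vocabulary has fewer than 2 terms after the "
            f"min_count={config.min_count} filter"
        )
    index = {t: i for i, t in enumerate(vocab)}

    rows, cols, vals = [], [], []
    for sent in sentences:
        ids = [index.get(t, -1) for t in sent]
        for i, wi in enumerate(ids):
            if wi < 0:
                continue
            hi = min(len(ids), i + 1 + config.window)
            for j in range(i + 1, hi):
                wj = ids[j]
                if wj < 0:
                    continue
                rows.extend((wi, wj))
                cols.extend((wj, wi))
                vals.extend((1.0, 1.0))
    n = len(vocab)
    C = sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()

    total = C.sum()
    if total == 0:
        raise ValueError("no in-window co-occurrences; corpus too small")
    row_sum = np.asarray(C.sum(axis=1)).ravel()
    # PPMI: max(0, log( p(i,j) / (p(i) p(j)) ))
    Cc = C.tocoo()
    with np.errstate(divide="ignore"):
        pmi = np.log(Cc.data * total / (row_sum[Cc.row] * row_sum[Cc.col]))
    pmi = np.maximum(pmi, 0.0)
    M = sp.coo_matrix((pmi, (Cc.row, Cc.col)), shape=(n, n))

    k = min(config.dimension, n - 1)
    # dense SVD below a size cutoff: exact and fully deterministic
    if n <= 2000:
        U, S, _ = np.linalg.svd(M.toarray(), full_matrices=False)
        U, S = U[:, :k], S[:k]
    else:
        U, S, _ = sp.linalg.svds(M.tocsc(), k=k, v0=np.full(n, 1.0 / n))
        order = np.argsort(-S)
        U, S = U[:, order], S[order]
    # fix SVD sign indeterminacy: largest |loading| per component positive
    signs = np.sign(U[np.argmax(np.abs(U), axis=0), np.arange(U.shape[1])])
    signs[signs == 0] = 1.0
    vecs = U * signs * np.sqrt(S)
    if vecs.shape[1] < config.dimension:
        pad = np.zeros((n, config.dimension - vecs.shape[1]))
        vecs = np.hstack([vecs, pad])
    return EmbeddingModel(vocab, vecs, config)


# ---------------------------------------------------------------------------
# seed expressions and lexicon

def default_seeds() -> dict[str, list[str]]:
    """Annotated seed expressions per cohesion theme, plus the core
    group-referential keywords."""
    return {
        "keywords": ["us", "we", "our group", "our", "group", "support"],
        "reassurance": ["encourage", "good for you", "proud"],
        "support": ["support", "sending hugs", "here for each other"],
        "disclosure_trust": ["trust", "share", "safe"],
        "belonging": ["belong", "part of this group"],
        "gratitude": ["thank you", "thanks", "grateful"],
        "shared_experience": ["in common", "same", "shared"],
        "positive_reflection": ["great group", "miss this group"],
        "future_anticipation": ["next week", "looking forward", "next session"],
    }


@dataclass
class CohesionLexicon:
    """Seed expressions plus embedding-expanded and human-added terms."""

    seeds: dict[str, list[str]]
    expanded: list[tuple[str, str, float]] = field(default_factory=list)
    human_added: list[str] = field(default_factory=list)
    min_similarity: float = DEFAULT_MIN_SIMILARITY

    def all_expressions(self) -> list[str]:
        out: list[str] = []
        for exprs in self.seeds.values():
            out.extend(exprs)
        out.extend(e for e, _, _ in self.expanded)
        out.extend(self.human_added)
        # stable dedup
        seen: set[str] = set()
        uniq = []
        for e in out:
            if e not in seen:
                seen.add(e)
                uniq.append(e)
        return uniq

    def __len__(self) -> int:
        return len(self.all_expressions())

    def match_count(self, tokens: Sequence[str]) -> int:
        """Number of lexicon expressions occurring in a token sequence
        (multi-word expressions matched as contiguous runs)."""
        joined = " " + " ".join(tokens) + " "
        return sum(
            1 for e in self.all_expressions() if f" {e.lower()} " in joined
        )

    # -- JSON round trip ----------------------------------------------------
    def to_json(self) -> str:
        return json.dumps(
            {
                "seeds": self.seeds,
                "expanded": [list(t) for t in self.expanded],
                "human_added": self.human_added,
                "min_similarity": self.min_similarity,
            },
            indent=2,
            ensure_ascii=False,
        )

    @classmethod
    def from_json(cls, text: str) -> "CohesionLexicon":
        d = json.loads(text)
        return cls(
            seeds={k: list(v) for k, v in d["seeds"].items()},
            expanded=[(e, s, float(x)) for e, s, x in d["expanded"]],
            human_added=list(d["human_added"]),
            min_similarity=float(d["min_similarity"]),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json(), encoding="utf-8")

    @classmethod
    def load(cls, path: str | Path) -> "CohesionLexicon":
        return cls.from_json(Path(path).read_text(encoding="utf-8"))


def expand_seeds(
    model: EmbeddingModel,
    seeds: Mapping[str, Sequence[str]] | Sequence[str],
    top_k: int = DEFAULT_TOP_K,
    min_similarity: float = DEFAULT_MIN_SIMILARITY,
) -> CohesionLexicon:
    """Expand seed expressions with their nearest in-vocabulary neighbors.

    Each seed contributes at most ``top_k`` expansions with cosine
    similarity >= ``min_similarity``; duplicates across seeds keep the
    highest-similarity attribution. Seeds with no token in vocabulary are
    skipped with a warning; if none are usable the call is rejected.
    """
    if not isinstance(seeds, Mapping):
        seeds = {"seeds": list(seeds)}
    seeds = {k: list(v) for k, v in seeds.items()}
    flat = [e for exprs in seeds.values() for e in exprs]
    seed_tokens = {t for e in flat for t in e.lower().split()}

    usable = 0
    best: dict[str, tuple[str, float]] = {}  # expansion -> (seed, sim)
    for seed in flat:
        if model.vector(seed) is None:
            logger.warning("seed %r has no in-vocabulary token; skipped", seed)
            continue
        usable += 1
        for term, sim in model.most_similar(seed, top_k=top_k, exclude=seed_tokens):
            if sim < min_similarity:
                break  # most_similar is sorted descending
            if term not in best or sim > best[term][1]:
                best[term] = (seed, sim)
    if usable == 0:
        raise ValueError("no seed expression has any in-vocabulary token")

    expanded = sorted(
        ((term, seed, sim) for term, (seed, sim) in best.items()),
        key=lambda t: (-t[2], t[0]),
    )
    return CohesionLexicon(
        seeds=seeds, expanded=expanded, min_similarity=min_similarity
    )
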