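"""TF-IDF ensemble classification of per-message cohesion.

Messages are vectorized with TF-IDF over unigrams and bigrams (vocabulary
capped at 5000 terms), optionally augmented with one engineered feature: the
number of cohesion-lexicon expressions matched in the message. Five
classifiers are trained — linear SVM, multinomial naive Bayes, a multilayer
perceptron, random forest, and logistic regression — and ranked by
positive-class F1 on a stratified 20% held-out split. The three best form
the voting ensemble: a message's final label is the one agreed by at least
2 of the 3, with a confidence equal to the F1-weighted share of the voters
that agreed, and a raw score equal to the mean positive-class probability.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import joblib
import numpy as np
import scipy.sparse as sp
from sklearn.feature_extraction.text import TfidfVectorizer
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import f1_score
from sklearn.model_selection import train_test_split
from sklearn.naive_bayes import MultinomialNB
from sklearn.neural_network import MLPClassifier
from sklearn.ensemble import RandomForestClassifier
from sklearn.calibration import CalibratedClassifierCV
from sklearn.svm import LinearSVC

from .lexicon import CohesionLexicon
from .preprocess import tokenize
from .synthetic_corpus import LabeledMessage, Message

POSITIVE = "cohesion"
NEGATIVE = "non_cohesion"

CLASSIFIER_NAMES = ("svm", "naive_bayes", "mlp", "random_forest", "logistic_regression")
N_SELECTED = 3


@dataclass(frozen=True)
class FeatureConfig:
    max_features: int = 5000
    ngram_range: tuple[int, int] = (1, 2)
    lexicon_feature: bool = True

    def __post_init__(self) -> None:
        if self.max_features < 1:
            raise ValueError("max_features must be >= 1")


@dataclass(frozen=True)
class ScoredMessage:
    message_id: str
    raw_score: float
    votes: dict[str, str]
    vote_label: str
    confidence: float


def _texts_and_ids(messages: Sequence) -> tuple[list[str], list[str]]:
    texts, ids = [], []
    for m in messages:
        if isinstance(m, LabeledMessage):
            m = m.message
        if isinstance(m, Message):
            ids.append(m.message_id)
            texts.append(m.text)
        else:  # (message_id, text) pair
            ids.append(str(m[0]))
            texts.append(str(m[1]))
    return texts, ids


def _build_classifiers(seed: int) -> dict:
    return {
        # linear SVM has no native probabilities; Platt-calibrate its
        # decision function (deterministic: unshuffled stratified folds)
        "svm": CalibratedClassifierCV(
            LinearSVC(random_state=seed), ensemble=False, cv=3
        ),
        "naive_bayes": MultinomialNB(),
        "mlp": MLPClassifier(
            hidden_layer_sizes=(100,), max_iter=500, random_state=seed
        ),
        "random_forest": RandomForestClassifier(n_estimators=100, random_state=seed),
        "logistic_regression": LogisticRegression(max_iter=1000, random_state=seed),
    }


def select_top3(val_f1: Mapping[str, float]) -> list[str]:
    """The 3 classifier names with highest F1; ties broken by name order."""
    return sorted(val_f1, key=lambda name: (-val_f1[name], name))[:N_SELECTED]


class EnsembleModel:
    """Fitted vectorizer + five classifiers + validation F1s + top-3 set."""

    def __init__(
        self,
        vectorizer: TfidfVectorizer,
        classifiers: dict,
        val_f1: dict[str, float],
        config: FeatureConfig,
        lexicon: CohesionLexicon | None,
        seed: int,
    ):
        self.vectorizer = vectorizer
        self.classifiers = classifiers
        self.val_f1 = val_f1
        self.selected = select_top3(val_f1)
        self.config = config
        self.lexicon = lexicon
        self.seed = seed

    # -- features -----------------------------------------------------------
    def _features(self, texts: Sequence[str]) -> sp.csr_matrix:
        X = self.vectorizer.transform(texts)
        if self.config.lexicon_feature and self.lexicon is not None:
            counts = np.array(
                [[self.lexicon.match_count(tokenize(t))] for t in texts], dtype=float
            )
            X = sp.hstack([X, sp.csr_matrix(counts)], format="csr")
        return X

    def positive_probabilities(self, texts: Sequence[str]) -> dict[str, np.ndarray]:
        """Positive-class probability per selected classifier."""
        X = self._features(texts)
        out = {}
        for name in self.selected:
            clf = self.classifiers[name]
            pos = list(clf.classes_).index(POSITIVE)
            out[name] = clf.predict_proba(X)[:, pos]
        return out

    # -- persistence ----------------------------------------------------------
    def save(self, model_dir: str | Path) -> None:
        d = Path(model_dir)
        d.mkdir(parents=True, exist_ok=True)
        joblib.dump(self.vectorizer, d / "vectorizer.joblib")
        for name, clf in self.classifiers.items():
            joblib.dump(clf, d / f"clf_{name}.joblib")
        if self.lexicon is not None:
            self.lexicon.save(d / "lexicon.json")
        manifest = {
            "val_f1": self.val_f1,
            "selected": self.selected,
            "seed": self.seed,
            "config": {
                "max_features": self.config.max_features,
                "ngram_range": list(self.config.ngram_range),
                "lexicon_feature": self.config.lexicon_feature,
            },
        }
        (d / "manifest.json").write_text(json.dumps(manifest, indent=2))

    @classmethod
    def load(cls, model_dir: str | Path) -> "EnsembleModel":
        d = Path(model_dir)
        manifest = json.loads((d / "manifest.json").read_text())
        cfg = FeatureConfig(
            max_features=manifest["config"]["max_features"],
            ngram_range=tuple(manifest["config"]["ngram_range"]),
            lexicon_feature=manifest["config"]["lexicon_feature"],
        )
        lex_path = d / "lexicon.json"
        lexicon = CohesionLexicon.load(lex_path) if lex_path.exists() else None
        classifiers = {
            name: joblib.load(d / f"clf_{name}.joblib") for name in CLASSIFIER_NAMES
        }
        return cls(
            vectorizer=joblib.load(d / "vectorizer.joblib"),
            classifiers=classifiers,
            val_f1=manifest["val_f1"],
            config=cfg,
            lexicon=lexicon,
            seed=manifest["seed"],
        )


def fit(
    train: Sequence[LabeledMessage],
    config: FeatureConfig = FeatureConfig(),
    seed: int = 0,
    lexicon: CohesionLexicon | None = None,
    val_fraction: float = 0.2,
) -> EnsembleModel:
    """Train the five classifiers and select the top 3 by held-out F1.

    Requires at least 20 labeled examples with both classes present. The
    held-out split is stratified and seeded; F1 is positive-class (cohesion)
    F1 on that split.
    """
    if len(train) < 20:
        raise ValueError(f"need >= 20 training examples, got {len(train)}")
    texts = [lm.message.text for lm in train]
    labels = np.array([lm.gold_label for lm in train])
    if len(set(labels)) < 2:
        raise ValueError("training data contains a single class; need both labels")

    tr_texts, va_texts, tr_y, va_y = train_test_split(
        texts, labels, test_size=val_fraction, stratify=labels, random_state=seed
    )
    vectorizer = TfidfVectorizer(
        max_features=config.max_features,
        ngram_range=config.ngram_range,
        tokenizer=tokenize,
        token_pattern=None,
        lowercase=True,
    )
    vectorizer.fit(tr_texts)

    model = EnsembleModel(
        vectorizer=vectorizer,
        classifiers=_build_classifiers(seed),
        val_f1={name: 0.0 for name in CLASSIFIER_NAMES},
        config=config,
        lexicon=lexicon if config.lexicon_feature else None,
        seed=seed,
    )
    Xtr = model._features(tr_texts)
    Xva = model._features(va_texts)
    for name, clf in model.classifiers.items():
        clf.fit(Xtr, tr_y)
        pred = clf.predict(Xva)
        model.val_f1[name] = float(f1_score(va_y, pred, pos_label=POSITIVE))
    model.selected = select_top3(model.val_f1)
    return model


def vote(
    probabilities: Mapping[str, float],
    val_f1: Mapping[str, float],
    decision_threshold: float = 0.5,
) -> tuple[str, float, float]:
    """2-of-3 majority vote with F1-weighted confidence.

    Each classifier votes positive iff its probability >= the threshold; the
    majority label wins. ``raw_score`` is the mean of the three
    probabilities; confidence is the F1 mass of the agreeing voters divided
    by the F1 mass of all three (1.0 when unanimous).
    """
    if len(probabilities) != N_SELECTED:
        raise ValueError(f"expected exactly {N_SELECTED} probabilities, got {len(probabilities)}")
    for name, p in probabilities.items():
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"probability for {name} out of [0,1]: {p}")
        if name not in val_f1:
            raise ValueError(f"no validation F1 for classifier {name}")
    labels = {
        name: (POSITIVE if p >= decision_threshold else NEGATIVE)
        for name, p in probabilities.items()
    }
    n_pos = sum(1 for v in labels.values() if v == POSITIVE)
    vote_label = POSITIVE if n_pos >= 2 else NEGATIVE
    raw_score = float(np.mean(list(probabilities.values())))
    total = sum(val_f1[name] for name in probabilities)
    agreeing = sum(val_f1[name] for name in probabilities if labels[name] == vote_label)
    confidence = agreeing / total if total > 0 else 1.0
    return vote_label, raw_score, confidence


def predict(model: EnsembleModel, messages: Sequence) -> list[ScoredMessage]:
    """Score messages with the fitted ensemble, preserving order."""
    if not getattr(model.vectorizer, "vocabulary_", None):
        raise ValueError("model is not fitted")
    if len(messages) == 0:
        return []
    texts, ids = _texts_and_ids(messages)
    probs = model.positive_probabilities(texts)
    out = []
    for i, mid in enumerate(ids):
        per_clf = {name: float(probs[name][i]) for name in model.selected}
        label, raw, conf = vote(per_clf, model.val_f1)
        out.append(
            ScoredMessage(
                message_id=mid,
                raw_score=raw,
                votes={
                    name: (POSITIVE if p >= 0.5 else NEGATIVE)
                    for name, p in per_clf.items()
                },
                vote_label=label,
                confidence=conf,
            )
        )
    return out
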