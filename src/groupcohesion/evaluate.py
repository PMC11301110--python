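"""Evaluation metrics and the human-in-the-loop active-learning cycle.

A round of active learning mirrors the study workflow: a systematic sample
(every 5th message) of the model's outputs is scored against gold labels,
a confusion matrix with precision / recall / F1 (positive class = cohesion)
is reported, terms recurring in the false-negative texts are appended to the
cohesion lexicon as human-added expressions, and the ensemble is refit on
the training data augmented with the newly labeled sample. Rounds repeat
until the F1 stop rule (>= 0.80) or a round cap.

Human scorers are abstracted as an oracle callback ``message_id -> label``;
:func:`oracle_from_csv` adapts a two-column CSV so real annotations can fill
the role.
"""

from __future__ import annotations

import csv
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

from . import classifier as clf_mod
from . import rules as rules_mod
from .classifier import EnsembleModel, FeatureConfig, POSITIVE
from .lexicon import CohesionLexicon
from .preprocess import sample_every_kth, tokenize
from .rules import RuleConfig
from .synthetic_corpus import LabeledMessage

DEFAULT_TARGET_F1 = 0.80
DEFAULT_STRIDE = 5
DEFAULT_MAX_ROUNDS = 5

# function words excluded from lexicon growth; everything here is either
# closed-class or already covered by the seed keywords
_STOPWORDS = frozenset(
    """
    a an the this that these those and or but if then than so to of in on at
    for from by with about as is are was were be been being am do does did
    have has had will would can could should may might must not no i me my
    we us our you your he she it they them his her its their there here what
    when who how why which s m re ve ll d t n't
    """.split()
)


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion matrix counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @classmethod
    def from_pairs(
        cls, predicted: Sequence[str], gold: Sequence[str]
    ) -> "ConfusionMatrix":
        if len(predicted) != len(gold):
            raise ValueError("predicted and gold must be the same length")
        tp = fp = fn = tn = 0
        for p, g in zip(predicted, gold):
            if p == POSITIVE and g == POSITIVE:
                tp += 1
            elif p == POSITIVE:
                fp += 1
            elif g == POSITIVE:
                fn += 1
            else:
                tn += 1
        return cls(tp=tp, fp=fp, fn=fn, tn=tn)


def metrics(cm: ConfusionMatrix) -> tuple[float | None, float | None, float]:
    """(precision, recall, F1) for the positive class.

    A denominator of zero leaves precision or recall undefined (None); F1 is
    the harmonic mean, 0 when precision + recall is 0. An all-zero matrix is
    rejected. Values are unrounded; round only at reporting time.
    """
    if cm.total == 0:
        raise ValueError("confusion matrix is all zeros")
    precision = cm.tp / (cm.tp + cm.fp) if (cm.tp + cm.fp) else None
    recall = cm.tp / (cm.tp + cm.fn) if (cm.tp + cm.fn) else None
    p = precision or 0.0
    r = recall or 0.0
    f1 = 2 * p * r / (p + r) if (p + r) > 0 else 0.0
    return precision, recall, f1


def f1_from_pr(precision: float, recall: float) -> float:
    """Harmonic mean of a printed precision/recall pair."""
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)


@dataclass(frozen=True)
class EvalReport:
    precision: float | None
    recall: float | None
    f1: float
    counts: ConfusionMatrix
    round_id: int
    # trap/theme -> list of message ids, split by error type
    false_positives: dict[str, list[str]] = field(default_factory=dict)
    false_negatives: dict[str, list[str]] = field(default_factory=dict)


def stop_rule(report: EvalReport, target_f1: float = DEFAULT_TARGET_F1) -> bool:
    """Stop once the report's F1 reaches the target (>= convention)."""
    return report.f1 >= target_f1


def render_table(rows: Sequence[tuple[str, EvalReport]]) -> str:
    """Plain-text performance table (Precision, Recall, F1 at 2 decimals)."""
    def cell(v: float | None) -> str:
        return "n/a" if v is None else f"{v:.2f}"

    lines = [f"{'Scoring round/method':<28}{'Precision':>10}{'Recall':>8}{'F1':>6}"]
    for name, rep in rows:
        lines.append(
            f"{name:<28}{cell(rep.precision):>10}{cell(rep.recall):>8}{cell(rep.f1):>6}"
        )
    return "\n".join(lines)


def oracle_from_csv(path: str | Path) -> Callable[[str], str]:
    """Adapter: a (message_id,label) CSV becomes an oracle callback."""
    table: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for row in csv.reader(fh):
            if not row or row[0] == "message_id":
                continue
            table[row[0]] = row[1]
    def oracle(message_id: str) -> str:
        return table[message_id]
    return oracle


# ---------------------------------------------------------------------------
# active learning

@dataclass
class RoundResult:
    model: EnsembleModel
    report: EvalReport
    lexicon: CohesionLexicon
    train: list[LabeledMessage]  # augmented training set after the round


def _final_labels(
    model: EnsembleModel,
    messages: Sequence[LabeledMessage],
    rule_config: RuleConfig,
) -> list[str]:
    scored = clf_mod.predict(model, messages)
    texts = [lm.message.text for lm in messages]
    adjusted = rules_mod.apply_rules(scored, texts, rule_config)
    return [a.final_label for a in adjusted]


def _novel_fn_terms(
    fn_texts: Sequence[str], lexicon: CohesionLexicon, min_freq: int = 2
) -> list[str]:
    known = {
        tok
        for expr in lexicon.all_expressions()
        for tok in tokenize(expr)
    }
    counts = Counter(
        tok
        for text in fn_texts
        for tok in tokenize(text)
        if tok.isalpha() and len(tok) > 1 and tok not in _STOPWORDS
    )
    return sorted(t for t, c in counts.items() if c >= min_freq and t not in known)


def active_learning_round(
    model: EnsembleModel,
    train: Sequence[LabeledMessage],
    unscored: Sequence[LabeledMessage],
    oracle: Callable[[str], str],
    lexicon: CohesionLexicon,
    k: int = DEFAULT_STRIDE,
    round_id: int = 1,
    feature_config: FeatureConfig | None = None,
    rule_config: RuleConfig = RuleConfig(),
    seed: int = 0,
) -> RoundResult:
    """One scoring-and-retraining cycle.

    Every ``k``-th message of ``unscored`` is scored by the oracle against
    the pipeline's final labels; the confusion matrix and error listing are
    reported; novel terms recurring in false-negative texts grow the lexicon
    (provenance ``human_added``); and the model is refit on ``train`` plus
    the freshly labeled sample. The oracle must cover every sampled id.
    """
    sample = sample_every_kth(unscored, k)
    predicted = _final_labels(model, sample, rule_config)
    gold = []
    for lm in sample:
        try:
            gold.append(oracle(lm.message.message_id))
        except KeyError:
            raise ValueError(
                f"oracle does not cover sampled message {lm.message.message_id!r}"
            ) from None
    cm = ConfusionMatrix.from_pairs(predicted, gold)
    precision, recall, f1 = metrics(cm)

    fps: dict[str, list[str]] = {}
    fns: dict[str, list[str]] = {}
    fn_texts = []
    for lm, p, g in zip(sample, predicted, gold):
        theme = lm.theme or "unknown"
        if p == POSITIVE and g != POSITIVE:
            fps.setdefault(theme, []).append(lm.message.message_id)
        elif p != POSITIVE and g == POSITIVE:
            fns.setdefault(theme, []).append(lm.message.message_id)
            fn_texts.append(lm.message.text)
    report = EvalReport(
        precision=precision,
        recall=recall,
        f1=f1,
        counts=cm,
        round_id=round_id,
        false_positives=fps,
        false_negatives=fns,
    )

    new_lexicon = CohesionLexicon(
        seeds={k_: list(v) for k_, v in lexicon.seeds.items()},
        expanded=list(lexicon.expanded),
        human_added=list(lexicon.human_added) + _novel_fn_terms(fn_texts, lexicon),
        min_similarity=lexicon.min_similarity,
    )

    scored_sample = [
        LabeledMessage(message=lm.message, gold_label=g, theme=lm.theme)
        for lm, g in zip(sample, gold)
    ]
    new_train = list(train) + scored_sample
    cfg = feature_config or model.config
    new_model = clf_mod.fit(new_train, cfg, seed=seed, lexicon=new_lexicon)
    return RoundResult(
        model=new_model, report=report, lexicon=new_lexicon, train=new_train
    )


def run_active_learning(
    model: EnsembleModel,
    train: Sequence[LabeledMessage],
    unscored: Sequence[LabeledMessage],
    oracle: Callable[[str], str],
    lexicon: CohesionLexicon,
    k: int = DEFAULT_STRIDE,
    max_rounds: int = DEFAULT_MAX_ROUNDS,
    target_f1: float = DEFAULT_TARGET_F1,
    rule_config: RuleConfig = RuleConfig(),
    seed: int = 0,
) -> tuple[EnsembleModel, list[EvalReport], CohesionLexicon]:
    """Iterate rounds on the same unscored pool until the F1 stop rule."""
    reports: list[EvalReport] = []
    cur_train = list(train)
    for r in range(1, max_rounds + 1):
        res = active_learning_round(
            model,
            cur_train,
            unscored,
            oracle,
            lexicon,
            k=k,
            round_id=r,
            rule_config=rule_config,
            seed=seed,
        )
        reports.append(res.report)
        model, lexicon, cur_train = res.model, res.lexicon, res.train
        if stop_rule(res.report, target_f1):
            break
    return model, reports, lexicon
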