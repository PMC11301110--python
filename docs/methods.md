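# Methods

This note documents the models, parameter choices and known limitations of
the `groupcohesion` pipeline, in the order the stages run.

## Synthetic transcript generator

The generator stands in for private OSG chat corpora. Each session is a
90-minute timeline with timestamps drawn as uniform order statistics (no
arrival model is assumed; a uniform exchangeable process is the simplest
choice and makes intervals directly comparable). Participants are assigned
uniformly from `n_participants`; every 10th post belongs to the facilitator,
reflecting a group of 6–10 members plus one therapist. Timestamps are stored
in seconds from session start; durations and interval lengths elsewhere in
the package are minutes.

Labels are generated in two steps: the gold label is Bernoulli with
parameter `cohesion_rate`, then with probability `trap_rate` the text is
drawn from a trap bank whose gold label matches (negated-cohesion and
outside-group-support traps are non-cohesive; idioms and "we"-less empathy
are cohesive). Drawing trap-vs-plain first would couple the realized
cohesion fraction to the trap mix; labeling first keeps the empirical
fraction binomial around `cohesion_rate`, which the tests verify at the
3·sqrt(p(1−p)/n) tolerance. The default `cohesion_rate` is 0.2 — a free
parameter, since no published base rate exists for this population — and
the test/acceptance corpora use 0.3 with `trap_rate` 0.1 so that every
theme and trap category is well represented at n = 2000.

Texts are slot-filled hand-written templates (intensifier, tense and
negation variants), seeded with the published example statements for each
theme and trap. This guarantees exact labels and byte-level reproducibility
from one integer seed, at the cost of realism: vocabulary is small (a few
hundred types), messages are grammatical and single-intent, and classes are
nearly separable. Passing tests on this corpus therefore demonstrate the
pipeline's mechanics (feature flow, voting, rules, aggregation), not
clinical-grade accuracy; saturated classifier F1 values are expected and
real transcripts will behave worse. Emojis are deliberately absent
(emoticons like `<3` are kept); multi-language text is out of scope.

## Tokenization and linguistic flags

A rule-based tokenizer lowercases, splits clitics (`didn't` → `did` +
`n't`), keeps punctuation as separate tokens and passes emoticons through.
The part-of-speech layer is a coarse closed-class tagger whose only
load-bearing output is the past-tense flag: a token is a past verb if it is
in an irregular-past list or ends in `-ed` (with a small exception list for
words like *indeed*, *sacred*). This over-triggers on adjectival participles
("I feel supported"), which is faithful to how a generic tagger feeds the
half-score rule; the cost is visible as false negatives in evaluation.

Negation, booster (intensifier), pronoun-person and empathy lexicons ship
as plain-text package data and can be overridden by file path; nothing is
downloaded at run time. Negation and person are message-global flags — no
scope resolution is attempted, so "I can't wait to chat with you all"
triggers the negation rule. This is a deliberate, documented bluntness of
the rule layer rather than a tokenizer defect.

## Embedding and lexicon expansion

The embedding is count-based: symmetric windowed co-occurrence counts
(window 10), PPMI weighting, truncated SVD with vectors `U·sqrt(S)`, sign
ambiguity fixed by orienting each component's largest loading positive.
Defaults: dimension 100, window 10, min_count 2. A closed-form factorization
was chosen over stochastic gradient training because it is exactly
reproducible, has no epoch/learning-rate tuning, and behaves well on the
small corpora this package targets; vectors are zero-padded when the
vocabulary rank is below the requested dimension so the dimension contract
holds on tiny inputs. The dense SVD path is used below 2000 vocabulary
types; above that a sparse Lanczos SVD with a fixed start vector keeps the
computation deterministic.

Seed expressions (per-theme lists plus *us*, *we*, *our group*) are
expanded with at most `top_k = 10` neighbors per seed at cosine
`min_similarity = 0.5` — conservative defaults, exposed in the API, since
no published cutoff exists. Multi-word seeds are embedded as the mean of
their in-vocabulary token vectors; seeds with no token in vocabulary are
skipped with a warning. How expanded expressions feed the classifier is an
open design point; here the count of lexicon-expression matches in a
message is appended as one engineered feature, an interpretation that keeps
the lexicon's influence inspectable.

## Ensemble

TF-IDF over unigrams + bigrams, vocabulary capped at 5000, shared
tokenizer. Five classifiers: Platt-calibrated linear SVM (linear SVMs have
no native probabilities; calibration uses unshuffled stratified folds for
determinism), multinomial naive Bayes, an MLP with one hidden layer of 100
units (max 500 iterations, seeded), a 100-tree random forest, and logistic
regression. Validation F1 (positive class = cohesion throughout) is
computed on a stratified seeded 20% split; the top 3 classifiers by that
F1 — ties broken by name — form the voting ensemble. The scheme is a 2-of-3
label majority; the mean positive probability is kept as the soft raw
score, and confidence is the F1 mass of agreeing voters over the F1 mass of
all three (1 iff unanimous).

## Rule layer

Order: negation (short-circuit to 0) → past tense ×0.5 → empathy ×2 →
intensifiers ×1.25 per booster, at most 2 counted → person flag → clamp to
[0, 1]; final label at threshold 0.5, overriding the vote when they differ
(rules must be able to veto, e.g. negation flipping a positive). Negation
first is forced by its "set to zero" semantics; the remaining rules are
multiplicative so their order is immaterial. The 1.25/cap-2 intensifier
magnitude is a package choice (no published value): one booster alone
cannot cross the 0.5 threshold from below 0.4, two cannot from below 0.32.
The second/third-person rule records the suppressed first-person flag but
multiplies by 1.0 by default — the conservative reading, since no score
effect is published for it. The rules operate on the ensemble's positive
probability; treating that probability as "the cohesion score" is a
recorded interpretation.

## Interval score β

β = |C| / |A| over half-open intervals [t, t+T) anchored at 0, T = 30
minutes by default, ceil(duration/T) intervals per session; a boundary post
belongs to the later interval and a post exactly at session end to the last
one. An empty interval yields β = null, not 0 — a dashboard reading 0 would
wrongly signal absent cohesion. Per-participant β restricts the same
formula to one participant's posts; both scopes are emitted.

## Dictionary-category baseline

The five categories ("we", positive emotion, family, friend, affiliation)
are matched with prefix wildcards over the shared tokenization; the
percentage denominator counts word tokens only. "Criterion met" is any
match (> 0%), and the label rule is fixed at 3 of 5. The shipped
dictionaries are small open stand-ins, not the proprietary LIWC lists; on
the synthetic corpus this baseline shows the expected keyword-dependence
failure modes (misses cohesive statements without "we"-language; fires on
family-support statements about people outside the group), and its absolute
recall is lower than a real LIWC run would give.

## Active learning

Every 5th message of the unscored pool is scored against the oracle; the
confusion matrix uses the pipeline's final (rule-adjusted) labels. Lexicon
growth takes tokens occurring ≥ 2 times in false-negative texts, excluding
function words and tokens already in the lexicon, with provenance
`human_added`. The model is refit on the training data plus the scored
sample. Rounds cap at 5 and stop at F1 ≥ 0.80 (inclusive). On synthetic
data, residual false negatives are mostly rule-layer vetoes (negation/past
tense inside genuinely cohesive statements), which retraining cannot fix;
recall therefore plateaus rather than degrades across rounds.

## Problem sizes and numerics

The test suite and the acceptance script run the full method at desk scale:
2000-message corpora (10 sessions × 200), 1000-message training splits, 200
replicate sessions for the β-recovery property, a 10,000-case fuzz of the
rule cascade. Floating-point comparisons in tests use relative tolerances
(~1e-6); β coverage uses the binomial 3σ band. All randomness flows from a
single integer seed per entry point (the CLI derives per-stage seeds as
`root·1000003 + stage_index mod 2^31`).

## Known limitations

- Message-global negation and person flags (no scope resolution).
- The coarse past-tense tagger over-triggers on adjectival participles.
- The stand-in dictionaries are much smaller than LIWC's categories.
- The synthetic corpus underestimates lexical diversity, typos, code-mixing
  and multi-intent messages; absolute metric levels do not transfer to real
  transcripts.
- Sarcasm, irony and emoji-borne affect are out of scope.
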