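# Methods

`notemia` is an auditing pipeline for a question that matters whenever
models trained on clinical free text are released: *does de-identification,
or replacement of the training text by LLM-generated synthetic notes,
actually prevent an attacker from inferring whether a given patient's note
was in the training set?*  The package implements the three interacting
pieces — a synthetic-note generation procedure driven by extracted key
phrases, a multilabel ICD-coding victim model, and a membership-inference
audit — together with a synthetic corpus generator that makes the whole
machinery runnable and testable without access to DUA-gated hospital data.

## The audit model

The attacker is a binary classifier that sees only the victim's per-label
prediction vector for a note and outputs a membership score (larger = more
member-like).  Following the single-shadow-model worst-case audit design,
the victim itself plays the shadow: prediction vectors of its own training
notes are labelled *member*, vectors of held-out notes *non-member*.

The scoring protocol (`mia_attack.run_trained_attack`) is:

1. **Balancing.**  If the classes are unequal, the larger one is subsampled
   uniformly without replacement to the size of the smaller; unselected
   samples of the larger class are the *leftover*.  (With 4033 members and
   1729 non-members this keeps 1729 per class and leaves 2304 members
   over.)
2. **Stratified, unshuffled 2-fold scoring.**  Fold membership is assigned
   positionally within each class in original input order.  Each fold is
   scored by an attack model trained on the other fold(s); leftover samples
   are scored by the final fold's attacker.  Every sample receives exactly
   one score (4033 + 1729 = 1729 + 1729 + 2304 in the example above).
3. **Attack models.**  A model-free threshold attack (score = mean
   per-label confidence margin, `mean_j |p_j − 0.5|`; the attacker has no
   ground-truth labels, so margin rather than loss) plus trained
   logistic-regression, 5-NN, 100-tree random-forest and one-hidden-layer
   (64) MLP attackers, all from scikit-learn with fixed documented
   hyperparameters.  Trained attackers score with their member-class
   probability.

Metrics: attacker **advantage** `max over ROC thresholds of (TPR − FPR)`
(in [0,1]; the degenerate thresholds achieve 0) and trapezoidal ROC
**AUC**.  The best model is the argmax of advantage with ties broken by a
fixed model order.

A calibration caveat worth knowing: when the member class is much larger
than the non-member class, most members (the leftovers) are scored by a
single fold's attacker.  Any calibration offset between fold attackers then
shows up as spurious advantage even for an untrained victim.  The audit
fixtures in this package therefore use train/test splits of comparable
size (0.45/0.1/0.45), which removes the artifact; the protocol itself is
implemented exactly as specified, leftover scoring included.

## The victim: recurrent encoder with per-label attention

The utility task is multilabel ICD coding over `L` codes (default 50).
Token embeddings (dim 32) feed a bidirectional recurrent encoder (vanilla
tanh cell, 32 units per direction); per-label attention follows the
label-attention ICD-coding architecture exactly:

    Z = tanh(H · W)            # shared projection, H: tokens × 2h
    A = softmax_tokens(Z · U)  # one attention column per label
    v_l = Σ_t A[t,l] · H[t]    # label-specific document vector
    logit_l = ⟨v_l, o_l⟩ + b_l # L independent binary outputs

Training minimizes summed per-label binary cross-entropy with Adam
(lr 2e-2, batch 32, global gradient-norm clipping at 5 — clipping is what
keeps long-sequence recurrent training stable here).  Everything is pure
numpy with hand-written backpropagation through time, validated against
finite differences in the test suite.  The vanilla recurrent cell (rather
than an LSTM) is a deliberate size/speed choice at desk scale; the
attention mechanism, which is the architecture's defining part, is exact.

Vocabulary is frequency-capped and built from the training split only;
notes are truncated to the first `max_note_tokens` whitespace tokens
(the note-length knob of the trade-off sweeps).  Masked (padded) positions
receive exactly zero attention, so predictions are independent of batching
and a saved model (deterministic zip container, fixed timestamps)
reproduces its prediction matrix bit for bit.

Early stopping, when enabled, only halts training; it does not restore the
best-validation weights.  That is intentional: the privacy audit needs the
overfitting behaviour of the final weights to remain observable.

## Key-phrase extraction and note generation

Generation is the reverse of summarization: extract the phrases that carry
the note's clinical content, then instruct a generator to write a new note
containing those phrases *in order*.

Extraction (per note): lowercase, delete numeric tokens, split punctuation;
candidates are all 1–3-grams that stay inside one punctuation-delimited
segment and do not start or end with a stopword.  Two scorers rank them:

* *frequency-position*: `tf × 1/(1 + first_offset/doc_length) × B^(n−1)`
  with multiword boost `B = 2`, after removing candidates below the
  least-allowable-seen-frequency (`lasf`, default 1);
* *multi-feature*: per-term badness
  `log2(2 + first_sentence) / (freq_norm × (1 + sentence_dispersion))`,
  combined as `Π badness / (tf × (1 + Σ badness))`; lower is better, and
  the exposed score is negated so "larger = better" holds everywhere.

The two scorers are formula-level implementations of the frequency/position
and multi-statistic extractor families; they use the published parameters
(max n-gram 3, lasf 1, de-duplication threshold 0.70) but do not chase
bit-parity with any reference library.  Top-⌈n/2⌉ phrases from each scorer
are merged (the odd remainder goes to the frequency-position scorer — the
apportionment is not specified anywhere, so it is a documented choice),
de-duplicated greedily in rank order using the edit ratio
`(|a|+|b|−Levenshtein)/(|a|+|b|)` at 0.70 (a sequence-matcher block ratio
is also available), ordered by first appearance, and truncated to `top_n`.
All ties break by (first offset, lexicographic) for determinism.

Prompts use one of two instruction wordings (`v0301`, `v0613`) with a
2250-word budget; completions are capped at 3000 tokens.  Token counts are
whitespace counts — a documented proxy, since the upstream model-tokenizer
is not part of this package.  The bundled generation backend is a
deterministic stub: each phrase is wrapped, in order, in seeded connective
sentences whose filler is drawn from the same clinical background
vocabulary the corpus generator uses (a fluent in-domain generator shares
its target domain's vocabulary; an out-of-domain stub would manufacture a
vocabulary shift no real LLM would produce).  Phrase tokens are never
altered, so in-order coverage is 1.0 by construction whenever the budget
allows.  A live-LLM adapter can implement the same `GenerationBackend`
contract but is outside the test surface.

In the synthetic-victim experiment the victim trains *only* on synthetic
counterparts of the train/validation notes (ids and label sets preserved),
utility is measured on the real test split, and — the crucial subtlety —
the membership dataset pairs the victim's predictions for the *real*
training notes against the *real* test notes: the audit asks whether
training on synthetic derivatives still leaks membership of their sources.

## The synthetic corpus

The generator emulates the statistical skeleton of a de-identified
discharge-summary corpus, not its language:

* `n_codes` labels with Zipf-like prevalence (`∝ 1/(rank+1)`, normalized);
* per-code signature phrases — three-token phrases assembled from a
  pseudo-clinical lexicon, unique to one code — spliced into filler
  sentences for each assigned code with probability
  `signature_injection_rate`; injected phrases occur once or twice, so
  genuine signal outranks one-off filler n-grams in frequency-based
  extraction, as diagnosis language does in real notes;
* label sets drawn per-code Bernoulli with prevalence-proportional rates
  (mean cardinality ≈ 3), resampled if empty;
* optional PHI surrogates: single bracketed sentinel tokens
  (`[**PHI-NAME**]`, `[**PHI-DATE**]`, `[**PHI-LOCATION**]`,
  `[**PHI-ID**]`), Poisson-many per note.  The placeholders are generic —
  a category but no patient-specific content — exactly as the bracketed
  placeholders of de-identified hospital corpora are.  By default they
  form a header block at the start of the note (like demographic front
  matter); an alternative `placement="random"` mode scatters them over
  sentence boundaries instead.  The header default is deliberate: real
  placeholders sit where the narrative puts them, whereas independently
  random positions stamp every note with an information-free but
  note-specific placement fingerprint, and an overfit victim demonstrably
  memorizes that fingerprint — scrubbing then reduces measured advantage
  by ~0.13, not because PHI *content* leaked but because the fixture
  manufactured an identification channel real text does not have.  The
  random mode is kept precisely so that channel can be studied.  Scrubbing
  removes exactly the sentinel tokens and is idempotent; signature phrases
  are never split in either mode.

What the fixtures deliberately control: injection rate 1.0 gives a fully
learnable coding task (the utility ceiling fixture); rate 0.6 leaves ~6% of
assigned codes with no textual evidence, creating the generalization gap
an overfit victim memorizes (the privacy fixtures).  What they do **not**
model: clinical language, real ICD-9 co-occurrence, inter-note dependence,
or any real-data distribution — so passing tests demonstrate correctness
and qualitative mechanism (overfitting → leakage; fewer phrases → less
utility), never real-world effect sizes.

## Problem sizes and numerical choices

Desk-scale defaults were chosen so the full audit ladder runs on one CPU:
corpora of 300–800 notes, 20 codes for the audit fixtures (50 remains the
package default), notes of 40–80 tokens, victim dims 32/32/32.  Trade-off
sweeps default to training sizes 800/600/400, truncation caps 256/192/96
and phrase budgets 40/20/10, preserving the 1 : 0.75 : 0.5-style ratios of
the full-scale design.  The audit fixtures use splits (0.45, 0.1, 0.45)
for the calibration reason above; the corpus default remains (0.7, 0.1,
0.2).

Numerical conventions: ROC AUC uses mid-rank tie handling (constant scores
give 0.5); labels with no positive (or no negative) test example are
excluded from the macro-AUC mean and counted in the report; F1/precision/
recall binarize at a configurable threshold (default 0.5) with the
zero-division-is-zero convention; precision@k breaks probability ties by
label index.  One master seed fixes every stage through named child seeds
(`crc32`-derived, below 2^31).

## Known limitations

* The no-signal null for the *pooled* micro-AUC is not 0.5 under a skewed
  label prior (prior-only ranking wins pooled pairs); per-label macro-AUC
  is the null-calibrated quantity and is what the no-signal test asserts.
* Attack-model hyperparameters are fixed defaults, not tuned per dataset;
  the reported "best" attacker is the argmax over this fixed family.
* The stub backend shares the corpus generator's vocabulary; transfer
  effects caused by genuine LLM vocabulary drift are out of scope.
* White-box attacks, multi-shadow-model attacks and differential-privacy
  defenses are out of scope by design.
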