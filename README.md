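# notemia

**Synthetic clinical note generation and membership-inference privacy
auditing for multilabel ICD coding models.**

Clinical notes are usually shared only after de-identification — removal of
the HIPAA-protected PHI tokens — or, increasingly, replaced altogether by
LLM-generated synthetic notes.  Neither step answers the question a privacy
auditor actually has to answer: *given black-box access to a model trained
on those notes, can an attacker tell whether a particular patient's note
was in the training set?*  `notemia` is a research pipeline for exactly
that audit.  It is written for privacy researchers and clinical-NLP
engineers who need a self-contained, deterministic, CPU-scale testbed: the
full machinery runs on a built-in synthetic corpus, with a deterministic
stand-in for the LLM backend, and no access to real patient data.

## What it implements

**The victim** is a multilabel ICD coder in the label-attention (LAAT)
family: token embeddings → bidirectional recurrent encoder → per-label
attention → `L` independent sigmoid outputs,

    Z = tanh(W·H),  A = softmax_tokens(U·Z),  v_l = Σ_t A[t,l]·H[t],
    logit_l = ⟨v_l, o_l⟩ + b_l,

trained with summed binary cross-entropy (pure numpy, hand-written
backpropagation through time, finite-difference-checked).

**The generation procedure** extracts key phrases from each real note with
two statistical scorers (frequency-position with multiword boost;
multi-feature position/frequency/dispersion badness), de-duplicates them
fuzzily at ratio 0.70, orders them by appearance, and prompts a backend to
"write a description of a patient … containing the following phrases
sequentially".  A deterministic offline stub fulfils the backend contract.

**The audit** is the single-shadow-model membership-inference protocol:
prediction vectors of training notes (members, `D_Shadow^Train`) vs
held-out notes (non-members, `D_Shadow^Out`); class balancing by uniform
subsampling without replacement; stratified unshuffled 2-fold scoring with
leftover samples scored by the final fold's attacker, so every sample is
scored exactly once; five attack models (threshold, logistic regression,
k-NN, random forest, MLP).  Reported: attacker **advantage**
`max(TPR − FPR)` and ROC **AUC**, next to micro/macro AUC / precision /
recall / F1 and precision@k for the utility side.

See `docs/methods.md` for the model equations, protocol details, fixture
design and known limitations.

## Worked example

`examples/05_membership_attack.py` trains two victims on the same 400-note
synthetic corpus — one early-stopped, one overfit — and audits both:

```
epochs=  5: test micro-F1 0.412 | best attacker random_forest advantage 0.183, AUC 0.594
epochs=100: test micro-F1 0.892 | best attacker threshold advantage 0.483, AUC 0.732
```

The overfit victim is far more useful (micro-F1 0.89 vs 0.41) *and* far
more leaky: an advantage of 0.48 means the best single score threshold
separates members from non-members 48 percentage points better than
guessing.  That coupling — utility and leakage rising together — is the
privacy/utility trade-off the pipeline is built to expose, and it persists
whether the victim is trained on raw notes, PHI-scrubbed notes, or
phrase-prompted synthetic notes (see the other examples and the sweep
command below).

Each capability has a short narrative script under `examples/`:
corpus generation, key-phrase extraction, offline note generation,
victim training/evaluation, and the attack suite.

## Command line

A thin CLI mirrors the library stage by stage:

```bash
notemia generate-corpus --n-notes 500 --n-codes 50 --seed 1 --out corpus.jsonl
notemia keyphrases      --in corpus.jsonl --top-n 20 --out phrases.jsonl
notemia gen-notes       --phrases phrases.jsonl --variant v0613 --seed 1 --out synth.jsonl
notemia train           --train train.jsonl --val val.jsonl --out model.bin
notemia predict         --model model.bin --notes test.jsonl --out preds.tsv
notemia evaluate        --preds preds.tsv --truth test.jsonl --out report.json
notemia attack          --member-preds train_preds.tsv --nonmember-preds preds.tsv --out attack.json
notemia sweep           --config run.yaml --out results/
```

All stages are deterministic given `--seed`; rerunning a stage reproduces
its output byte for byte.  Corpora are JSON-lines, prediction matrices
tab-delimited text, reports JSON.

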