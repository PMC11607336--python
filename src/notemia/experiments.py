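"""Experiment orchestration: real-victim audit, synthetic-victim audit,
and privacy/utility trade-off sweeps.

Three designs are exposed:

* :func:`run_real_experiment` — the victim trains on real (optionally
  de-identified) notes; membership is audited between its training notes
  (members) and test notes (non-members).
* :func:`run_synthetic_experiment` — key phrases are extracted from the
  real train+validation notes, a generation backend writes synthetic
  counterparts (ids and label sets preserved), and the victim trains only
  on synthetic text.  Utility is still measured on the real test split,
  and — the crucial subtlety — the membership dataset pairs the victim's
  prediction vectors for the *real* training notes (members) against the
  *real* test notes (non-members): the audit asks whether training on
  synthetic derivatives still leaks membership of the real sources.
* :func:`run_tradeoff_sweep` — a grid over training-set size × note
  length (and optionally key-phrase count) with seed replicates, emitting
  a tidy table of utility and attack metrics.

One master seed fixes every stage through named child seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from notemia._seeding import child_seed
from notemia.corpus_synth import CodeSpec, Note
from notemia.errors import ValidationError
from notemia.icd_classifier import (
    ClassifierConfig,
    TrainedClassifier,
    predict_probabilities,
    train_classifier,
)
from notemia.keyphrase import ExtractorConfig
from notemia.metrics import UtilityReport, micro_macro_report
from notemia.mia_attack import (
    AttackConfig,
    AttackReport,
    MembershipDataset,
    run_attack_suite,
)
from notemia.notegen import GenerationBackend, StubBackend, synthesize_corpus

__all__ = [
    "SweepConfig",
    "split_corpus",
    "run_real_experiment",
    "run_synthetic_experiment",
    "run_tradeoff_sweep",
]


@dataclass(frozen=True)
class SweepConfig:
    """Desk-scale sweep grid preserving the study's size/length ratios
    (1 : 0.75 : 0.5 over training sizes, 1 : 0.75 : 0.375 over lengths,
    1 : 0.5 : 0.25 over key-phrase counts)."""

    training_set_sizes: tuple[int, ...] = (800, 600, 400)
    max_note_tokens_values: tuple[int, ...] = (256, 192, 96)
    key_phrase_counts: tuple[int, ...] = (40, 20, 10)
    n_seed_replicates: int = 3

    def __post_init__(self):
        all_values = (
            self.training_set_sizes
            + self.max_note_tokens_values
            + self.key_phrase_counts
            + (self.n_seed_replicates,)
        )
        if any(v < 1 for v in all_values):
            raise ValidationError("all sweep values must be positive")


def split_corpus(corpus: list[Note]) -> tuple[list[Note], list[Note], list[Note]]:
    """Partition a corpus into its (train, val, test) splits."""
    train = [n for n in corpus if n.split == "train"]
    val = [n for n in corpus if n.split == "val"]
    test = [n for n in corpus if n.split == "test"]
    if not train or not val or not test:
        raise ValidationError("corpus must contain train, val and test notes")
    return train, val, test


def _label_matrix(notes: list[Note], label_codes: tuple[str, ...]) -> np.ndarray:
    index = {c: i for i, c in enumerate(label_codes)}
    y = np.zeros((len(notes), len(label_codes)))
    for i, note in enumerate(notes):
        for code in note.codes:
            y[i, index[code]] = 1.0
    return y


def _audit(
    victim: TrainedClassifier,
    member_notes: list[Note],
    nonmember_notes: list[Note],
    test_notes: list[Note],
    attack_config: AttackConfig,
) -> tuple[UtilityReport, AttackReport]:
    """Utility on the test notes plus the membership attack suite."""
    y_test = _label_matrix(test_notes, victim.label_codes)
    test_probs = predict_probabilities(victim, test_notes)
    ks = tuple(k for k in (1, 5, 8, 10, 15) if k <= victim.config.n_labels)
    utility = micro_macro_report(
        y_test, test_probs, threshold=victim.config.decision_threshold, ks=ks
    )
    member_probs = predict_probabilities(victim, member_notes)
    nonmember_probs = (
        test_probs
        if nonmember_notes is test_notes
        else predict_probabilities(victim, nonmember_notes)
    )
    dataset = MembershipDataset(
        member_vectors=member_probs, nonmember_vectors=nonmember_probs
    )
    attack = run_attack_suite(dataset, attack_config)
    return utility, attack


def run_real_experiment(
    corpus: list[Note],
    universe: list[CodeSpec],
    classifier_config: ClassifierConfig,
    attack_config: AttackConfig,
) -> tuple[UtilityReport, AttackReport]:
    """Audit a victim trained on the real training notes.

    Members are the victim's training notes, non-members the test notes;
    utility is measured on the test split.
    """
    train, val, test = split_corpus(corpus)
    victim = train_classifier(train, val, universe, classifier_config)
    return _audit(victim, train, test, test, attack_config)


def run_synthetic_experiment(
    corpus: list[Note],
    universe: list[CodeSpec],
    keyphrase_config: ExtractorConfig,
    backend: GenerationBackend,
    classifier_config: ClassifierConfig,
    attack_config: AttackConfig,
    variant: str = "v0613",
    seed: int = 0,
    max_completion_tokens: int = 3000,
) -> tuple[UtilityReport, AttackReport]:
    """Audit a victim trained only on synthetic counterparts.

    Synthetic notes are generated for the real train and validation notes
    (phrases extracted per note; ids/labels preserved).  The victim never
    sees real training text; utility uses the real test split and the
    membership dataset pairs real-train against real-test prediction
    vectors.
    """
    train, val, test = split_corpus(corpus)
    synth_train = synthesize_corpus(
        train, keyphrase_config, backend, variant=variant,
        seed=child_seed(seed, "synth-train"),
        max_completion_tokens=max_completion_tokens,
    )
    synth_val = synthesize_corpus(
        val, keyphrase_config, backend, variant=variant,
        seed=child_seed(seed, "synth-val"),
        max_completion_tokens=max_completion_tokens,
    )
    victim = train_classifier(synth_train, synth_val, universe, classifier_config)
    # Membership audit runs on REAL notes on both sides.
    return _audit(victim, train, test, test, attack_config)


_SWEEP_METRIC_COLUMNS = (
    "micro_auc", "macro_auc", "micro_precision", "macro_precision",
    "micro_recall", "macro_recall", "micro_f1", "macro_f1",
    "p_at_1", "p_at_5", "p_at_8", "p_at_10", "p_at_15",
    "attacker_advantage", "attack_auc",
)


def _sweep_row(utility: UtilityReport, attack: AttackReport) -> dict:
    best = attack.metrics[attack.best_model]
    row = {
        k: v for k, v in utility.as_dict().items()
        if k in _SWEEP_METRIC_COLUMNS or k.startswith("p_at_")
    }
    row["attacker_advantage"] = best.advantage
    row["attack_auc"] = best.auc
    return row


def run_tradeoff_sweep(
    corpus: list[Note],
    universe: list[CodeSpec],
    sweep: SweepConfig,
    classifier_config: ClassifierConfig,
    attack_config: AttackConfig,
    keyphrase_config: ExtractorConfig | None = None,
    backend: GenerationBackend | None = None,
    variant: str = "v0613",
    master_seed: int = 0,
) -> pd.DataFrame:
    """Grid sweep over training size × note length (+ key-phrase count).

    Emits one detail row per configuration per seed replicate plus one
    summary row (mean, with ``_sd`` companions) per configuration, sorted
    by training size then note length, both descending — the layout of the
    trade-off tables this pipeline is built to produce.  The key-phrase
    sweep (run when a backend is supplied) varies the prompt budget at the
    largest size/length configuration.
    """
    train, val, test = split_corpus(corpus)
    rows: list[dict] = []

    for size in sorted(sweep.training_set_sizes, reverse=True):
        if size > len(train):
            raise ValidationError(
                f"training_set_size {size} exceeds available {len(train)} train notes"
            )
        for max_tokens in sorted(sweep.max_note_tokens_values, reverse=True):
            for rep in range(sweep.n_seed_replicates):
                rep_seed = child_seed(master_seed, f"sweep:{size}:{max_tokens}:{rep}")
                rng = np.random.default_rng(rep_seed)
                subset_idx = np.sort(rng.choice(len(train), size=size, replace=False))
                subset = [train[i] for i in subset_idx]
                cfg = replace(
                    classifier_config, max_note_tokens=max_tokens, seed=rep_seed
                )
                victim = train_classifier(subset, val, universe, cfg)
                utility, attack = _audit(
                    victim, subset, test, test,
                    replace(attack_config, seed=rep_seed),
                )
                rows.append({
                    "sweep_kind": "real",
                    "train_size": size,
                    "max_tokens": max_tokens,
                    "top_n": None,
                    "replicate": rep,
                    "stat": "detail",
                    **_sweep_row(utility, attack),
                })

    if backend is not None:
        if keyphrase_config is None:
            keyphrase_config = ExtractorConfig()
        for top_n in sorted(sweep.key_phrase_counts, reverse=True):
            for rep in range(sweep.n_seed_replicates):
                rep_seed = child_seed(master_seed, f"sweep:kp:{top_n}:{rep}")
                kp_cfg = replace(keyphrase_config, top_n=top_n)
                utility, attack = run_synthetic_experiment(
                    corpus, universe, kp_cfg, backend,
                    replace(classifier_config, seed=rep_seed),
                    replace(attack_config, seed=rep_seed),
                    variant=variant, seed=rep_seed,
                )
                rows.append({
                    "sweep_kind": "synthetic",
                    "train_size": len(train),
                    "max_tokens": classifier_config.max_note_tokens,
                    "top_n": top_n,
                    "replicate": rep,
                    "stat": "detail",
                    **_sweep_row(utility, attack),
                })

    detail = pd.DataFrame(rows)
    group_cols = ["sweep_kind", "train_size", "max_tokens", "top_n"]
    metric_cols = [c for c in detail.columns if c in _SWEEP_METRIC_COLUMNS]
    summaries = []
    for keys, group in detail.groupby(group_cols, dropna=False, sort=False):
        summary = dict(zip(group_cols, keys))
        summary.update({"replicate": -1, "stat": "summary"})
        for col in metric_cols:
            summary[col] = float(group[col].mean())
            summary[f"{col}_sd"] = float(group[col].std(ddof=0))
        summaries.append(summary)
    table = pd.concat([detail, pd.DataFrame(summaries)], ignore_index=True)
    return table.sort_values(
        by=["sweep_kind", "train_size", "max_tokens", "replicate"],
        ascending=[True, False, False, True],
        kind="stable",
    ).reset_index(drop=True)


# Re-export for CLI convenience.
default_stub_backend = StubBackend
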