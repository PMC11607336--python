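"""Membership-inference attack framework.

The attacker sees only the victim classifier's per-label prediction vectors
and must decide, per note, whether it was in the victim's training set.
Following the single-shadow-model audit design, the victim itself plays the
shadow model: prediction vectors of its training notes are labelled
*member* (``D_Shadow^Train``) and of held-out notes *non-member*
(``D_Shadow^Out``).

Protocol (worst-case leakage audit):

1. **Balance** — the larger class is subsampled uniformly without
   replacement down to the smaller; the leftover samples are recorded.
2. **Stratified, unshuffled k-fold scoring** (default 2 folds) — fold
   assignment is positional within each class in original order; each fold
   is scored by an attack model trained on the remaining folds, and the
   leftover samples are scored by the final fold's attacker, so every
   sample receives exactly one membership score.
3. **Attack models** — a model-free threshold attack (mean per-label
   confidence margin) plus trained logistic-regression, k-NN,
   random-forest and multi-layer-perceptron attackers; scores are oriented
   so larger = more member-like (trained models emit member-class
   probability).

Example of the protocol arithmetic: with 4033 member and 1729 non-member
vectors, 1729 members are sampled for balance, 2304 members are left over,
and 1729 + 1729 + 2304 scores are assigned, each sample exactly once.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier

from notemia.errors import ProtocolError, ValidationError
from notemia.metrics import AttackMetrics, attack_metrics

__all__ = [
    "MembershipDataset",
    "AttackConfig",
    "BalancedAttackData",
    "AttackReport",
    "MODEL_ORDER",
    "balance_attack_data",
    "attack_features",
    "threshold_attack",
    "run_trained_attack",
    "run_attack_suite",
]

#: Fixed model-name order (also the tie-break order for the best model).
MODEL_ORDER = ("threshold", "logistic", "knn", "random_forest", "mlp")


@dataclass(frozen=True)
class MembershipDataset:
    """Victim prediction vectors for members and non-members."""

    member_vectors: np.ndarray      # (m, L)
    nonmember_vectors: np.ndarray   # (k, L)
    multilabel: bool = True

    def __post_init__(self):
        m = np.asarray(self.member_vectors, dtype=float)
        k = np.asarray(self.nonmember_vectors, dtype=float)
        if m.ndim != 2 or k.ndim != 2 or m.shape[1] != k.shape[1]:
            raise ValidationError(
                f"vector groups must be 2-D with equal width: {m.shape}, {k.shape}"
            )
        if m.shape[0] < 1 or k.shape[0] < 1:
            raise ValidationError("each group needs at least one sample")
        for arr, name in ((m, "member"), (k, "nonmember")):
            if arr.min() < 0 or arr.max() > 1:
                raise ValidationError(f"{name} probabilities must lie in [0, 1]")
        object.__setattr__(self, "member_vectors", m)
        object.__setattr__(self, "nonmember_vectors", k)

    @property
    def n_members(self) -> int:
        return self.member_vectors.shape[0]

    @property
    def n_nonmembers(self) -> int:
        return self.nonmember_vectors.shape[0]

    @property
    def membership_labels(self) -> np.ndarray:
        """1 for every member, 0 for every non-member, in storage order."""
        return np.concatenate(
            [np.ones(self.n_members, dtype=int), np.zeros(self.n_nonmembers, dtype=int)]
        )


@dataclass(frozen=True)
class AttackConfig:
    """Which attack models to run and how."""

    attack_models: tuple[str, ...] = MODEL_ORDER
    balance: bool = True
    n_folds: int = 2
    seed: int = 0

    def __post_init__(self):
        if not self.attack_models:
            raise ValidationError("at least one attack model is required")
        unknown = set(self.attack_models) - set(MODEL_ORDER)
        if unknown:
            raise ValidationError(f"unknown attack models: {sorted(unknown)}")
        if self.n_folds < 2:
            raise ValidationError(f"n_folds must be >= 2, got {self.n_folds}")


@dataclass(frozen=True)
class BalancedAttackData:
    """Index bookkeeping of the balancing step.

    Indices are within-class (0-based into each vector group) and kept in
    ascending order so downstream fold assignment is positional in the
    original input order ("unshuffled").
    """

    member_indices: np.ndarray
    nonmember_indices: np.ndarray
    leftover_indices: np.ndarray
    leftover_class: int  # 1 = members were larger, 0 = non-members, -1 = none


@dataclass(frozen=True)
class AttackReport:
    """Per-model attack metrics and per-sample membership scores."""

    metrics: dict[str, AttackMetrics]
    scores: dict[str, np.ndarray] = field(repr=False)
    best_model: str = ""
    n_members: int = 0
    n_nonmembers: int = 0

    def as_dict(self) -> dict:
        return {
            "best_model": self.best_model,
            "n_members": self.n_members,
            "n_nonmembers": self.n_nonmembers,
            "models": {
                name: {"advantage": m.advantage, "auc": m.auc}
                for name, m in self.metrics.items()
            },
        }


def balance_attack_data(
    dataset: MembershipDataset, rng: np.random.Generator
) -> BalancedAttackData:
    """Equalize class sizes by uniform sampling without replacement.

    ``min(m, k)`` samples are kept per class; the larger class's unselected
    samples are the leftover.  Selected indices are sorted so the original
    within-class order is preserved for fold assignment.
    """
    m, k = dataset.n_members, dataset.n_nonmembers
    n_keep = min(m, k)
    member_idx = np.arange(m)
    nonmember_idx = np.arange(k)
    if m > k:
        member_idx = np.sort(rng.choice(m, size=n_keep, replace=False))
        leftover = np.setdiff1d(np.arange(m), member_idx)
        leftover_class = 1
    elif k > m:
        nonmember_idx = np.sort(rng.choice(k, size=n_keep, replace=False))
        leftover = np.setdiff1d(np.arange(k), nonmember_idx)
        leftover_class = 0
    else:
        leftover = np.empty(0, dtype=int)
        leftover_class = -1
    return BalancedAttackData(
        member_indices=member_idx,
        nonmember_indices=nonmember_idx,
        leftover_indices=leftover,
        leftover_class=leftover_class,
    )


def attack_features(vectors: np.ndarray, multilabel: bool = True) -> np.ndarray:
    """Feature map applied to prediction vectors before attack training.

    Multilabel victims expose the full probability vector unchanged;
    single-label victims expose the descending-sorted probabilities
    (class-order invariant confidence profile).
    """
    vectors = np.atleast_2d(np.asarray(vectors, dtype=float))
    if multilabel:
        return vectors
    return -np.sort(-vectors, axis=1)


def threshold_attack(dataset: MembershipDataset) -> np.ndarray:
    """Model-free attack: score = mean per-label confidence margin.

    ``score_i = mean_j |p_ij − 0.5|`` — confident (near 0/1) prediction
    vectors look member-like.  Returns one score per sample, members first.
    """
    all_vectors = np.vstack([dataset.member_vectors, dataset.nonmember_vectors])
    return np.abs(all_vectors - 0.5).mean(axis=1)


def _make_attack_model(model_type: str, seed: int):
    if model_type == "logistic":
        return LogisticRegression(max_iter=1000, random_state=seed)
    if model_type == "knn":
        return KNeighborsClassifier(n_neighbors=5)
    if model_type == "random_forest":
        return RandomForestClassifier(n_estimators=100, random_state=seed, n_jobs=1)
    if model_type == "mlp":
        return MLPClassifier(
            hidden_layer_sizes=(64,), max_iter=200, random_state=seed
        )
    raise ValidationError(f"unknown trained attack model: {model_type!r}")


def run_trained_attack(
    dataset: MembershipDataset,
    model_type: str,
    config: AttackConfig,
    balanced: BalancedAttackData | None = None,
) -> np.ndarray:
    """Score every sample once via the stratified-fold protocol.

    Returns an array of length ``m + k`` (members first, then non-members,
    in original order): balanced samples are scored by the attacker that
    held them out; leftover samples of the larger class are scored by the
    final fold's attacker.
    """
    if balanced is None:
        rng = np.random.default_rng(config.seed)
        balanced = (
            balance_attack_data(dataset, rng)
            if config.balance
            else BalancedAttackData(
                member_indices=np.arange(dataset.n_members),
                nonmember_indices=np.arange(dataset.n_nonmembers),
                leftover_indices=np.empty(0, dtype=int),
                leftover_class=-1,
            )
        )

    member_feat = attack_features(dataset.member_vectors, dataset.multilabel)
    nonmember_feat = attack_features(dataset.nonmember_vectors, dataset.multilabel)

    x = np.vstack(
        [member_feat[balanced.member_indices], nonmember_feat[balanced.nonmember_indices]]
    )
    y = np.concatenate(
        [
            np.ones(len(balanced.member_indices), dtype=int),
            np.zeros(len(balanced.nonmember_indices), dtype=int),
        ]
    )
    # Global positions of the balanced samples in the (members, nonmembers)
    # concatenation that the returned score array is indexed by.
    global_pos = np.concatenate(
        [balanced.member_indices, dataset.n_members + balanced.nonmember_indices]
    )

    scores = np.full(dataset.n_members + dataset.n_nonmembers, np.nan)
    folds = StratifiedKFold(n_splits=config.n_folds, shuffle=False)
    try:
        fold_pairs = list(folds.split(x, y))
    except ValueError as exc:
        raise ProtocolError(f"cannot build stratified folds: {exc}") from exc
    last_model = None
    for fold_train, fold_test in fold_pairs:
        if len(np.unique(y[fold_train])) < 2 or len(np.unique(y[fold_test])) < 2:
            raise ProtocolError("a stratified fold contains a single class")
        model = _make_attack_model(model_type, config.seed)
        model.fit(x[fold_train], y[fold_train])
        member_col = int(np.flatnonzero(model.classes_ == 1)[0])
        scores[global_pos[fold_test]] = model.predict_proba(x[fold_test])[:, member_col]
        last_model = model

    if len(balanced.leftover_indices):
        if balanced.leftover_class == 1:
            feats = member_feat[balanced.leftover_indices]
            pos = balanced.leftover_indices
        else:
            feats = nonmember_feat[balanced.leftover_indices]
            pos = dataset.n_members + balanced.leftover_indices
        member_col = int(np.flatnonzero(last_model.classes_ == 1)[0])
        scores[pos] = last_model.predict_proba(feats)[:, member_col]

    assert not np.isnan(scores).any(), "protocol bug: some sample left unscored"
    return scores


def run_attack_suite(dataset: MembershipDataset, config: AttackConfig) -> AttackReport:
    """Run every configured attack model and report per-model metrics.

    The balancing draw is shared across models so their scores are
    comparable; the best model is the argmax of advantage with ties broken
    by the fixed model-name order.
    """
    rng = np.random.default_rng(config.seed)
    balanced = (
        balance_attack_data(dataset, rng)
        if config.balance
        else None
    )
    labels = dataset.membership_labels

    metrics: dict[str, AttackMetrics] = {}
    scores: dict[str, np.ndarray] = {}
    for name in MODEL_ORDER:
        if name not in config.attack_models:
            continue
        if name == "threshold":
            model_scores = threshold_attack(dataset)
        else:
            model_scores = run_trained_attack(dataset, name, config, balanced=balanced)
        scores[name] = model_scores
        metrics[name] = attack_metrics(model_scores, labels)

    best = max(
        metrics, key=lambda name: (metrics[name].advantage, -MODEL_ORDER.index(name))
    )
    return AttackReport(
        metrics=metrics,
        scores=scores,
        best_model=best,
        n_members=dataset.n_members,
        n_nonmembers=dataset.n_nonmembers,
    )
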