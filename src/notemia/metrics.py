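"""Utility and attack metrics.

Utility (multilabel classification): micro-averaged metrics treat every
(note, code) pair as one prediction pooled over the whole matrix;
macro-averaged metrics are unweighted means of per-label values.
Precision/recall/F1 binarize probabilities at a decision threshold, AUC is
threshold-free.  Precision@k averages, over notes, the fraction of the k
highest-probability labels that are true.

Attack (membership inference): the attacker's advantage is
``max over ROC thresholds of (TPR − FPR)`` — the best single-threshold
accuracy gain over guessing — together with the trapezoidal ROC AUC.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import (
    auc as _trapezoid_auc,
    precision_recall_fscore_support,
    roc_auc_score,
    roc_curve,
)

from notemia.errors import ValidationError

__all__ = [
    "UtilityReport",
    "AttackMetrics",
    "micro_macro_report",
    "precision_at_k",
    "attack_metrics",
]

DEFAULT_KS = (1, 5, 8, 10, 15)


@dataclass(frozen=True)
class UtilityReport:
    """Micro/macro AUC, precision, recall, F1 and P@k for one classifier."""

    micro_auc: float
    macro_auc: float
    micro_precision: float
    macro_precision: float
    micro_recall: float
    macro_recall: float
    micro_f1: float
    macro_f1: float
    precision_at_k: dict[int, float]
    n_notes: int
    n_labels: int
    decision_threshold: float
    n_labels_excluded_from_macro_auc: int = 0

    def as_dict(self) -> dict:
        return {
            "micro_auc": self.micro_auc,
            "macro_auc": self.macro_auc,
            "micro_precision": self.micro_precision,
            "macro_precision": self.macro_precision,
            "micro_recall": self.micro_recall,
            "macro_recall": self.macro_recall,
            "micro_f1": self.micro_f1,
            "macro_f1": self.macro_f1,
            **{f"p_at_{k}": v for k, v in sorted(self.precision_at_k.items())},
            "n_notes": self.n_notes,
            "n_labels": self.n_labels,
            "decision_threshold": self.decision_threshold,
        }


@dataclass(frozen=True)
class AttackMetrics:
    """Attacker advantage (max TPR−FPR) and ROC AUC."""

    advantage: float
    auc: float
    roc_fpr: tuple[float, ...] = field(default_factory=tuple, repr=False)
    roc_tpr: tuple[float, ...] = field(default_factory=tuple, repr=False)


def _mid_rank_auc(y_true: np.ndarray, y_score: np.ndarray) -> float:
    """ROC AUC with mid-rank tie handling (constant scores give 0.5)."""
    return float(roc_auc_score(y_true, y_score))


def micro_macro_report(
    y_true: np.ndarray,
    y_prob: np.ndarray,
    threshold: float = 0.5,
    ks: tuple[int, ...] = DEFAULT_KS,
) -> UtilityReport:
    """Full multilabel utility report.

    Labels with no positive (or no negative) example in ``y_true`` have an
    undefined AUC and are excluded from the macro-AUC mean; the count of
    exclusions is surfaced in the report.
    """
    y_true = np.asarray(y_true, dtype=int)
    y_prob = np.asarray(y_prob, dtype=float)
    if y_true.shape != y_prob.shape or y_true.ndim != 2:
        raise ValidationError(
            f"shape mismatch: y_true {y_true.shape} vs y_prob {y_prob.shape}"
        )
    n, n_labels = y_true.shape
    y_pred = (y_prob >= threshold).astype(int)

    micro_p, micro_r, micro_f1, _ = precision_recall_fscore_support(
        y_true, y_pred, average="micro", zero_division=0
    )
    macro_p, macro_r, macro_f1, _ = precision_recall_fscore_support(
        y_true, y_pred, average="macro", zero_division=0
    )

    micro_auc = _mid_rank_auc(y_true.ravel(), y_prob.ravel())

    per_label_auc = []
    excluded = 0
    for j in range(n_labels):
        positives = int(y_true[:, j].sum())
        if positives == 0 or positives == n:
            excluded += 1
            continue
        per_label_auc.append(_mid_rank_auc(y_true[:, j], y_prob[:, j]))
    if not per_label_auc:
        raise ValidationError("macro AUC undefined: every label is single-class")

    return UtilityReport(
        micro_auc=micro_auc,
        macro_auc=float(np.mean(per_label_auc)),
        micro_precision=float(micro_p),
        macro_precision=float(macro_p),
        micro_recall=float(micro_r),
        macro_recall=float(macro_r),
        micro_f1=float(micro_f1),
        macro_f1=float(macro_f1),
        precision_at_k=precision_at_k(y_true, y_prob, ks),
        n_notes=n,
        n_labels=n_labels,
        decision_threshold=threshold,
        n_labels_excluded_from_macro_auc=excluded,
    )


def precision_at_k(
    y_true: np.ndarray, y_prob: np.ndarray, ks: tuple[int, ...] = DEFAULT_KS
) -> dict[int, float]:
    """Average precision of the top-k predicted labels per note.

    Ties in probability break by lower label index (stable sort).
    """
    y_true = np.asarray(y_true, dtype=int)
    y_prob = np.asarray(y_prob, dtype=float)
    n, n_labels = y_true.shape
    for k in ks:
        if not 1 <= k <= n_labels:
            raise ValidationError(f"k={k} outside [1, {n_labels}]")
    order = np.argsort(-y_prob, axis=1, kind="stable")
    result: dict[int, float] = {}
    for k in ks:
        top = order[:, :k]
        hits = np.take_along_axis(y_true, top, axis=1).sum(axis=1)
        result[k] = float(np.mean(hits / k))
    return result


def attack_metrics(scores: np.ndarray, membership_labels: np.ndarray) -> AttackMetrics:
    """ROC-derived attack metrics over all score thresholds.

    ``advantage = max(TPR − FPR)`` with tied scores grouped (so it is
    always in [0, 1]; the degenerate all-or-nothing thresholds achieve 0).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(membership_labels, dtype=int)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValidationError("scores and labels must be equal-length 1-D arrays")
    if len(np.unique(labels)) < 2:
        raise ValidationError("membership labels contain a single class")
    fpr, tpr, _ = roc_curve(labels, scores, drop_intermediate=False)
    return AttackMetrics(
        advantage=float(np.max(tpr - fpr)),
        auc=float(_trapezoid_auc(fpr, tpr)),
        roc_fpr=tuple(float(v) for v in fpr),
        roc_tpr=tuple(float(v) for v in tpr),
    )
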