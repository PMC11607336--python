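"""Independent brute-force oracles used to pin down metric semantics.

Everything here is written as plainly as possible — explicit loops,
exhaustive threshold enumeration, O(n^2) pair counting — so the tests can
compare the package's vectorized implementations against an obviously
correct computation.
"""

from __future__ import annotations

import math


def micro_counts(y_true, y_pred):
    """Pooled TP/FP/FN over every (note, label) pair."""
    tp = fp = fn = 0
    for row_true, row_pred in zip(y_true, y_pred):
        for t, p in zip(row_true, row_pred):
            if p and t:
                tp += 1
            elif p and not t:
                fp += 1
            elif not p and t:
                fn += 1
    return tp, fp, fn


def prf(tp, fp, fn):
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = (
        2 * precision * recall / (precision + recall) if precision + recall else 0.0
    )
    return precision, recall, f1


def macro_prf(y_true, y_pred):
    n_labels = len(y_true[0])
    sums = [0.0, 0.0, 0.0]
    for j in range(n_labels):
        col_true = [row[j] for row in y_true]
        col_pred = [row[j] for row in y_pred]
        values = prf(*micro_counts([[t] for t in col_true], [[p] for p in col_pred]))
        for i in range(3):
            sums[i] += values[i]
    return tuple(s / n_labels for s in sums)


def pairwise_auc(y_true, scores):
    """AUC by exhaustive pair counting; ties count one half."""
    pos = [s for t, s in zip(y_true, scores) if t]
    neg = [s for t, s in zip(y_true, scores) if not t]
    if not pos or not neg:
        raise ValueError("AUC undefined for single-class input")
    wins = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                wins += 1.0
            elif p == n:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def precision_at_k_oracle(y_true, y_prob, k):
    """Average top-k precision; probability ties break by label index."""
    total = 0.0
    for row_true, row_prob in zip(y_true, y_prob):
        order = sorted(
            range(len(row_prob)), key=lambda j: (-row_prob[j], j)
        )[:k]
        total += sum(row_true[j] for j in order) / k
    return total / len(y_true)


def max_advantage(scores, labels):
    """max(TPR − FPR) by enumerating every distinct score threshold."""
    n_pos = sum(labels)
    n_neg = len(labels) - n_pos
    best = 0.0
    thresholds = sorted(set(scores)) + [math.inf]
    for thr in thresholds:
        tp = sum(1 for s, y in zip(scores, labels) if y and s >= thr)
        fp = sum(1 for s, y in zip(scores, labels) if not y and s >= thr)
        best = max(best, tp / n_pos - fp / n_neg)
    return best


def longest_increasing_subsequence(values):
    """Length of the longest strictly increasing subsequence, O(n^2)."""
    if not values:
        return 0
    best = [1] * len(values)
    for i in range(len(values)):
        for j in range(i):
            if values[j] < values[i]:
                best[i] = max(best[i], best[j] + 1)
    return max(best)


def edit_distance(a, b):
    """Classic O(nm) Levenshtein distance."""
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, start=1):
        cur = [i]
        for j, cb in enumerate(b, start=1):
            cur.append(
                min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (ca != cb))
            )
        prev = cur
    return prev[len(b)]


def ngrams_oracle(text, max_n, stopwords):
    """Brute-force candidate enumeration over punctuation-free segments.

    Returns ``{gram: (term_freq, first_offset)}``.
    """
    import re

    tokens = []
    for match in re.finditer(r"\S+", text):
        tokens.append((match.group(), match.start()))
    segments, current = [], []
    for tok, off in tokens:
        if not any(ch.isalnum() for ch in tok):
            if current:
                segments.append(current)
            current = []
        else:
            current.append((tok, off))
    if current:
        segments.append(current)

    grams = {}
    for segment in segments:
        words = [t for t, _ in segment]
        offsets = [o for _, o in segment]
        for n in range(1, max_n + 1):
            for i in range(len(words) - n + 1):
                gram = tuple(words[i : i + n])
                if gram[0] in stopwords or gram[-1] in stopwords:
                    continue
                freq, first = grams.get(gram, (0, offsets[i]))
                grams[gram] = (freq + 1, min(first, offsets[i]))
    return grams
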