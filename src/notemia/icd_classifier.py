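"""Multilabel ICD coding victim model: BiRNN encoder + per-label attention.

The architecture follows the label-attention family of ICD coders: token
embeddings feed a bidirectional recurrent encoder; a shared projection
``Z = tanh(W·H)`` and per-label scoring vectors ``U`` produce one attention
distribution over tokens per label; each label's document vector is the
attention-weighted sum of hidden states and feeds an independent binary
output (L sigmoid classifiers trained with summed binary cross-entropy).

The implementation is pure numpy with hand-written backpropagation through
time, sized for desk-scale corpora (defaults: embedding 32, hidden 32 per
direction, attention 32).  A vanilla tanh recurrent cell is used; the
attention equations are the architecture's defining part and are
implemented exactly.  Everything is seeded: parameter init, data order,
and hence the whole loss trajectory.

Prediction is a pure function of (model, notes): masked positions receive
exactly zero attention, so probabilities are independent of batch
composition and padding, and a reloaded model reproduces its prediction
matrix bit-identically.
"""

from __future__ import annotations

import io
import json
import zipfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from notemia.corpus_synth import CodeSpec, Note
from notemia.errors import ValidationError
from notemia.metrics import micro_macro_report

__all__ = [
    "ClassifierConfig",
    "TrainedClassifier",
    "build_vocabulary",
    "vectorize_note",
    "label_attention",
    "train_classifier",
    "predict_probabilities",
    "save_classifier",
    "load_classifier",
]

PAD_ID = 0
UNK_ID = 1

_MASKED_LOGIT = -1e30


@dataclass(frozen=True)
class ClassifierConfig:
    """Victim model hyperparameters (desk-scale defaults)."""

    vocab_size: int = 5000
    embedding_dim: int = 32
    recurrent_hidden_dim: int = 32   # per direction
    attention_dim: int = 32
    n_labels: int = 50
    max_note_tokens: int = 256
    epochs: int = 20
    batch_size: int = 32
    learning_rate: float = 2e-2
    decision_threshold: float = 0.5
    early_stop_patience: int | None = None
    seed: int = 0

    def __post_init__(self):
        dims = (
            self.vocab_size, self.embedding_dim, self.recurrent_hidden_dim,
            self.attention_dim, self.n_labels, self.max_note_tokens,
            self.epochs, self.batch_size,
        )
        if any(d < 1 for d in dims):
            raise ValidationError("all dimensions and counts must be positive")
        if not 0 < self.decision_threshold < 1:
            raise ValidationError("decision_threshold must be in (0,1)")


@dataclass
class TrainedClassifier:
    """A trained victim: vocabulary, parameters, and training metadata."""

    config: ClassifierConfig
    label_codes: tuple[str, ...]
    vocabulary: dict[str, int]
    params: dict[str, np.ndarray]
    training_log: list[dict] = field(default_factory=list)


def build_vocabulary(texts: list[str], vocab_size: int) -> dict[str, int]:
    """Frequency-capped vocabulary from training texts only.

    Ids 0 and 1 are reserved for padding and unknown tokens; the remaining
    slots go to the most frequent tokens (ties broken lexicographically).
    """
    counts: dict[str, int] = {}
    for text in texts:
        for token in text.split():
            counts[token] = counts.get(token, 0) + 1
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    vocab = {"<pad>": PAD_ID, "<unk>": UNK_ID}
    for token, _count in ranked[: max(vocab_size - 2, 0)]:
        vocab[token] = len(vocab)
    return vocab


def vectorize_note(
    text: str, vocabulary: dict[str, int], max_note_tokens: int
) -> np.ndarray:
    """Map whitespace tokens to ids, truncating to the first ``max`` tokens.

    Unknown tokens map to the reserved unknown id; an empty text maps to a
    single padding id so every note has length >= 1.
    """
    ids = [vocabulary.get(t, UNK_ID) for t in text.split()[:max_note_tokens]]
    if not ids:
        ids = [PAD_ID]
    return np.asarray(ids, dtype=np.int64)


def _init_params(config: ClassifierConfig, rng: np.random.Generator) -> dict:
    d, h, a, ll = (
        config.embedding_dim,
        config.recurrent_hidden_dim,
        config.attention_dim,
        config.n_labels,
    )

    def uniform(*shape, fan_in):
        bound = 1.0 / np.sqrt(fan_in)
        return rng.uniform(-bound, bound, size=shape)

    return {
        "E": uniform(config.vocab_size, d, fan_in=d),
        "Wx_f": uniform(d, h, fan_in=d),
        "Wh_f": uniform(h, h, fan_in=h),
        "b_f": np.zeros(h),
        "Wx_b": uniform(d, h, fan_in=d),
        "Wh_b": uniform(h, h, fan_in=h),
        "b_b": np.zeros(h),
        "W_att": uniform(2 * h, a, fan_in=2 * h),
        "U_att": uniform(a, ll, fan_in=a),
        "O": uniform(ll, 2 * h, fan_in=2 * h),
        "b_o": np.zeros(ll),
    }


def _run_direction(g, mask, wx, wh, b, reverse: bool):
    """One direction of the recurrent encoder; masked steps hold state."""
    n, t_len, _ = g.shape
    h_dim = wh.shape[0]
    states = np.zeros((n, t_len, h_dim))
    h = np.zeros((n, h_dim))
    steps = range(t_len - 1, -1, -1) if reverse else range(t_len)
    for t in steps:
        m = mask[:, t : t + 1]
        h = m * np.tanh(g[:, t] @ wx + h @ wh + b) + (1.0 - m) * h
        states[:, t] = h
    return states


def _forward(params, x, mask):
    """Full forward pass; returns probabilities and a cache for backprop."""
    g = params["E"][x]                                   # (B,T,d)
    h_f = _run_direction(g, mask, params["Wx_f"], params["Wh_f"], params["b_f"], False)
    h_b = _run_direction(g, mask, params["Wx_b"], params["Wh_b"], params["b_b"], True)
    hidden = np.concatenate([h_f, h_b], axis=2)          # (B,T,2h)

    z = np.tanh(hidden @ params["W_att"])                # (B,T,a)
    s = z @ params["U_att"]                              # (B,T,L)
    s = np.where(mask[:, :, None] > 0, s, _MASKED_LOGIT)
    s_max = s.max(axis=1, keepdims=True)
    exp_s = np.exp(s - s_max)
    attn = exp_s / exp_s.sum(axis=1, keepdims=True)      # (B,T,L)

    ctx = np.einsum("btl,bth->blh", attn, hidden)        # (B,L,2h)
    logits = np.einsum("blh,lh->bl", ctx, params["O"]) + params["b_o"]
    probs = 1.0 / (1.0 + np.exp(-logits))
    cache = {"g": g, "x": x, "mask": mask, "h_f": h_f, "h_b": h_b,
             "hidden": hidden, "z": z, "attn": attn, "ctx": ctx, "probs": probs}
    return probs, cache


def _backward(params, cache, y):
    """Gradients of mean-over-batch summed-BCE loss w.r.t. every parameter."""
    g, x, mask = cache["g"], cache["x"], cache["mask"]
    hidden, z, attn, ctx, probs = (
        cache["hidden"], cache["z"], cache["attn"], cache["ctx"], cache["probs"]
    )
    n, t_len, _ = g.shape
    h_dim = params["Wh_f"].shape[0]
    grads = {k: np.zeros_like(v) for k, v in params.items()}

    dlogits = (probs - y) / n                                   # (B,L)
    grads["b_o"] = dlogits.sum(axis=0)
    grads["O"] = np.einsum("bl,blh->lh", dlogits, ctx)
    dctx = dlogits[:, :, None] * params["O"][None, :, :]        # (B,L,2h)

    dattn = np.einsum("blh,bth->btl", dctx, hidden)             # (B,T,L)
    dhidden = np.einsum("btl,blh->bth", attn, dctx)             # (B,T,2h)

    # softmax over tokens, independently per (sample, label)
    ds = attn * (dattn - (attn * dattn).sum(axis=1, keepdims=True))
    grads["U_att"] = np.einsum("bta,btl->al", z, ds)
    dz = np.einsum("btl,al->bta", ds, params["U_att"])
    dz_pre = dz * (1.0 - z**2)
    grads["W_att"] = np.einsum("bth,bta->ha", hidden, dz_pre)
    dhidden += dz_pre @ params["W_att"].T

    dg = np.zeros_like(g)

    def bptt(states, d_states, wx, wh, reverse):
        dwx = np.zeros_like(wx)
        dwh = np.zeros_like(wh)
        db = np.zeros(h_dim)
        carry = np.zeros((n, h_dim))
        steps = range(t_len) if reverse else range(t_len - 1, -1, -1)
        for t in steps:
            m = mask[:, t : t + 1]
            dh = d_states[:, t] + carry
            dpre = dh * (1.0 - states[:, t] ** 2) * m
            dwx += g[:, t].T @ dpre
            prev_t = t + 1 if reverse else t - 1
            if 0 <= prev_t < t_len:
                dwh += states[:, prev_t].T @ dpre
            db += dpre.sum(axis=0)
            dg[:, t] += dpre @ wx.T
            carry = dpre @ wh.T + dh * (1.0 - m)
        return dwx, dwh, db

    grads["Wx_f"], grads["Wh_f"], grads["b_f"] = bptt(
        cache["h_f"], dhidden[:, :, :h_dim], params["Wx_f"], params["Wh_f"], False
    )
    grads["Wx_b"], grads["Wh_b"], grads["b_b"] = bptt(
        cache["h_b"], dhidden[:, :, h_dim:], params["Wx_b"], params["Wh_b"], True
    )

    np.add.at(grads["E"], x, dg)
    return grads


def label_attention(
    hidden_states: np.ndarray, params: dict[str, np.ndarray]
) -> tuple[np.ndarray, np.ndarray]:
    """Per-label attention over one note's hidden states.

    Given ``H`` of shape (tokens, hidden), computes ``Z = tanh(H·W)``,
    per-label attention weights ``softmax_t(Z·U)`` and per-label document
    vectors (the attention-weighted sums of hidden states).  Returns
    ``(label_vectors, attention_weights)`` of shapes (L, hidden) and
    (tokens, L).
    """
    hidden_states = np.asarray(hidden_states, dtype=float)
    if hidden_states.ndim != 2 or hidden_states.shape[0] == 0:
        raise ValidationError("hidden_states must be a non-empty (tokens, hidden) array")
    z = np.tanh(hidden_states @ params["W_att"])
    s = z @ params["U_att"]                              # (T,L)
    s = s - s.max(axis=0, keepdims=True)
    attn = np.exp(s)
    attn /= attn.sum(axis=0, keepdims=True)
    vectors = attn.T @ hidden_states                     # (L,hidden)
    return vectors, attn


def _pad_batch(sequences: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    t_len = max(len(s) for s in sequences)
    x = np.full((len(sequences), t_len), PAD_ID, dtype=np.int64)
    mask = np.zeros((len(sequences), t_len))
    for i, seq in enumerate(sequences):
        x[i, : len(seq)] = seq
        mask[i, : len(seq)] = 1.0
    return x, mask


class _Adam:
    def __init__(self, params, lr):
        self.lr = lr
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params, grads, beta1=0.9, beta2=0.999, eps=1e-8, max_norm=5.0):
        # Global-norm gradient clipping keeps recurrent training stable on
        # longer sequences.
        norm = np.sqrt(sum(float((g**2).sum()) for g in grads.values()))
        if norm > max_norm:
            scale = max_norm / norm
            grads = {k: g * scale for k, g in grads.items()}
        self.t += 1
        correction = np.sqrt(1 - beta2**self.t) / (1 - beta1**self.t)
        for k in params:
            self.m[k] = beta1 * self.m[k] + (1 - beta1) * grads[k]
            self.v[k] = beta2 * self.v[k] + (1 - beta2) * grads[k] ** 2
            params[k] -= self.lr * correction * self.m[k] / (np.sqrt(self.v[k]) + eps)


def _label_matrix(notes: list[Note], label_index: dict[str, int]) -> np.ndarray:
    y = np.zeros((len(notes), len(label_index)))
    for i, note in enumerate(notes):
        for code in note.codes:
            y[i, label_index[code]] = 1.0
    return y


def train_classifier(
    train_notes: list[Note],
    val_notes: list[Note],
    universe: list[CodeSpec],
    config: ClassifierConfig,
) -> TrainedClassifier:
    """Train the victim by minimizing summed per-label binary cross-entropy.

    The vocabulary is built from the training split only.  Validation
    micro-F1 is tracked every epoch; if ``early_stop_patience`` is set,
    training halts after that many epochs without improvement (final
    weights are the last epoch's — intentionally, so overfitting behaviour
    stays observable for privacy audits).
    """
    if not train_notes or not val_notes:
        raise ValidationError("train and validation splits must be non-empty")
    label_codes = tuple(s.code for s in universe)
    if len(label_codes) != config.n_labels:
        raise ValidationError(
            f"config.n_labels={config.n_labels} != |universe|={len(label_codes)}"
        )
    label_index = {c: i for i, c in enumerate(label_codes)}
    for note in train_notes + val_notes:
        outside = note.codes - set(label_codes)
        if outside:
            raise ValidationError(
                f"note {note.note_id!r} has labels outside the universe: "
                f"{sorted(outside)}"
            )

    rng = np.random.default_rng(config.seed)
    vocab = build_vocabulary([n.text for n in train_notes], config.vocab_size)
    x_train = [vectorize_note(n.text, vocab, config.max_note_tokens) for n in train_notes]
    y_train = _label_matrix(train_notes, label_index)
    y_val = _label_matrix(val_notes, label_index)

    params = _init_params(config, rng)
    optimizer = _Adam(params, config.learning_rate)
    model = TrainedClassifier(
        config=config, label_codes=label_codes, vocabulary=vocab, params=params
    )

    best_val_f1, best_epoch = -1.0, -1
    for epoch in range(config.epochs):
        order = rng.permutation(len(x_train))
        epoch_loss = 0.0
        for start in range(0, len(order), config.batch_size):
            idx = order[start : start + config.batch_size]
            x, mask = _pad_batch([x_train[i] for i in idx])
            y = y_train[idx]
            probs, cache = _forward(params, x, mask)
            p = np.clip(probs, 1e-12, 1 - 1e-12)
            epoch_loss += float(
                -(y * np.log(p) + (1 - y) * np.log(1 - p)).sum()
            )
            grads = _backward(params, cache, y)
            optimizer.step(params, grads)
        epoch_loss /= len(x_train)

        val_probs = predict_probabilities(model, val_notes)
        val_f1 = micro_macro_report(
            y_val, val_probs, threshold=config.decision_threshold, ks=(1,)
        ).micro_f1
        model.training_log.append(
            {"epoch": epoch, "train_loss": epoch_loss, "val_micro_f1": val_f1}
        )
        if val_f1 > best_val_f1:
            best_val_f1, best_epoch = val_f1, epoch
        elif (
            config.early_stop_patience is not None
            and epoch - best_epoch >= config.early_stop_patience
        ):
            break
    return model


def predict_probabilities(
    model: TrainedClassifier, notes: list[Note], batch_size: int = 256
) -> np.ndarray:
    """Per-label probabilities for each note; deterministic given the model."""
    cfg = model.config
    out = np.zeros((len(notes), cfg.n_labels))
    for start in range(0, len(notes), batch_size):
        chunk = notes[start : start + batch_size]
        seqs = [
            vectorize_note(n.text, model.vocabulary, cfg.max_note_tokens)
            for n in chunk
        ]
        x, mask = _pad_batch(seqs)
        probs, _ = _forward(model.params, x, mask)
        out[start : start + len(chunk)] = probs
    return out


# ---------------------------------------------------------------------------
# Serialization: a versioned zip container with fixed timestamps, so the
# same model always produces byte-identical files.

_FORMAT_VERSION = 1


def save_classifier(model: TrainedClassifier, path: str | Path) -> None:
    """Write the model as a deterministic zip of JSON metadata + arrays."""
    meta = {
        "format_version": _FORMAT_VERSION,
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in vars(model.config).items()
        },
        "label_codes": list(model.label_codes),
        "vocabulary": model.vocabulary,
        "training_log": model.training_log,
        "param_names": sorted(model.params),
    }
    with zipfile.ZipFile(path, "w", compression=zipfile.ZIP_DEFLATED) as zf:
        def add(name: str, payload: bytes):
            info = zipfile.ZipInfo(name, date_time=(1980, 1, 1, 0, 0, 0))
            info.compress_type = zipfile.ZIP_DEFLATED
            zf.writestr(info, payload)

        add("meta.json", json.dumps(meta, sort_keys=True).encode("utf-8"))
        for name in sorted(model.params):
            buf = io.BytesIO()
            np.lib.format.write_array(
                buf, np.ascontiguousarray(model.params[name]), version=(1, 0)
            )
            add(f"params/{name}.npy", buf.getvalue())


def load_classifier(path: str | Path) -> TrainedClassifier:
    """Reload a saved model; predictions are bit-identical to the original."""
    with zipfile.ZipFile(path) as zf:
        meta = json.loads(zf.read("meta.json"))
        if meta["format_version"] != _FORMAT_VERSION:
            raise ValidationError(
                f"unsupported model format version {meta['format_version']}"
            )
        cfg_raw = dict(meta["config"])
        params = {
            name: np.lib.format.read_array(io.BytesIO(zf.read(f"params/{name}.npy")))
            for name in meta["param_names"]
        }
    return TrainedClassifier(
        config=ClassifierConfig(**cfg_raw),
        label_codes=tuple(meta["label_codes"]),
        vocabulary={k: int(v) for k, v in meta["vocabulary"].items()},
        params=params,
        training_log=list(meta["training_log"]),
    )
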