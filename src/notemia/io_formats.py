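"""Readers and writers: JSON-lines corpora, delimited prediction matrices,
and the YAML run configuration.

All serialization is deterministic (stable key order, fixed float format)
so identical runs produce byte-identical files.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from notemia.corpus_synth import Note
from notemia.errors import ConfigError, ParseError, ValidationError

__all__ = [
    "RunConfig",
    "read_notes",
    "write_notes",
    "read_prediction_matrix",
    "write_prediction_matrix",
    "load_config",
]


# ---------------------------------------------------------------------------
# Notes (JSON-lines, one object per line, UTF-8)

def write_notes(notes: list[Note], path: str | Path) -> None:
    """Write one JSON object per note with stable key order."""
    with open(path, "w", encoding="utf-8") as fh:
        for note in notes:
            record = {
                "note_id": note.note_id,
                "text": note.text,
                "codes": sorted(note.codes),
                "split": note.split,
            }
            fh.write(json.dumps(record, sort_keys=True, ensure_ascii=False) + "\n")


def read_notes(path: str | Path) -> list[Note]:
    """Read a JSON-lines corpus; loses nothing written by :func:`write_notes`."""
    notes: list[Note] = []
    seen: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                record = json.loads(line)
                note = Note(
                    note_id=record["note_id"],
                    text=record["text"],
                    codes=frozenset(record["codes"]),
                    split=record["split"],
                )
            except (json.JSONDecodeError, KeyError, TypeError) as exc:
                raise ParseError(f"malformed note record ({exc})", lineno) from exc
            if note.note_id in seen:
                raise ValidationError(f"duplicate note_id {note.note_id!r}")
            seen.add(note.note_id)
            notes.append(note)
    return notes


# ---------------------------------------------------------------------------
# Prediction matrices (tab-delimited text, header row of label codes)

def write_prediction_matrix(
    note_ids: list[str],
    probabilities: np.ndarray,
    path: str | Path,
    labels: list[str] | None = None,
) -> None:
    """Write per-note label probabilities as tab-delimited text.

    Header: ``note_id`` followed by the label codes.  Values are written
    with 17 significant digits, enough to round-trip float64 exactly.
    """
    probs = np.asarray(probabilities, dtype=float)
    if probs.ndim != 2:
        raise ValidationError(f"probabilities must be 2-D, got shape {probs.shape}")
    if len(note_ids) != probs.shape[0]:
        raise ValidationError(
            f"{len(note_ids)} note ids but {probs.shape[0]} probability rows"
        )
    if probs.size and (probs.min() < 0 or probs.max() > 1):
        raise ValidationError("probabilities must lie in [0, 1]")
    if labels is None:
        labels = [f"label_{j}" for j in range(probs.shape[1])]
    if len(labels) != probs.shape[1]:
        raise ValidationError(f"{len(labels)} labels but {probs.shape[1]} columns")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("note_id\t" + "\t".join(labels) + "\n")
        for nid, row in zip(note_ids, probs):
            fh.write(nid + "\t" + "\t".join(f"{v:.17g}" for v in row) + "\n")


def read_prediction_matrix(
    path: str | Path,
) -> tuple[list[str], list[str], np.ndarray]:
    """Read a prediction matrix: (note_ids, labels, n×L array)."""
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n")
        if not header.startswith("note_id"):
            raise ParseError("missing 'note_id' header", 1)
        labels = header.split("\t")[1:]
        note_ids: list[str] = []
        rows: list[list[float]] = []
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(labels) + 1:
                raise ValidationError(
                    f"line {lineno}: expected {len(labels) + 1} fields, "
                    f"got {len(parts)}"
                )
            note_ids.append(parts[0])
            try:
                rows.append([float(v) for v in parts[1:]])
            except ValueError as exc:
                raise ParseError(f"non-numeric value ({exc})", lineno) from exc
    matrix = np.array(rows, dtype=float) if rows else np.empty((0, len(labels)))
    if matrix.size and (matrix.min() < 0 or matrix.max() > 1):
        raise ValidationError("probabilities must lie in [0, 1]")
    return note_ids, labels, matrix


# ---------------------------------------------------------------------------
# Run configuration

@dataclass
class RunConfig:
    """Fully-resolved pipeline configuration: one section per stage.

    Every section is optional in the YAML file; omitted keys take the
    documented defaults.  Unknown sections or keys are rejected by name.
    """

    seed: int = 0
    corpus: dict[str, Any] = field(default_factory=dict)
    keyphrase: dict[str, Any] = field(default_factory=dict)
    notegen: dict[str, Any] = field(default_factory=dict)
    classifier: dict[str, Any] = field(default_factory=dict)
    attack: dict[str, Any] = field(default_factory=dict)
    sweep: dict[str, Any] = field(default_factory=dict)


# Known keys per section, used to reject misspellings early instead of
# silently ignoring them.  Kept in sync with the config dataclasses.
_KNOWN_KEYS: dict[str, set[str]] = {
    "corpus": {
        "n_notes", "n_codes", "mean_codes_per_note", "note_length_tokens",
        "signature_injection_rate", "phi_rate", "split_fractions", "seed",
        "phrases_per_code",
    },
    "keyphrase": {
        "max_ngram", "lasf", "dedup_threshold", "top_n", "multiword_boost",
        "dedup_method",
    },
    "notegen": {"variant", "word_budget", "max_completion_tokens", "backend"},
    "classifier": {
        "vocab_size", "embedding_dim", "recurrent_hidden_dim", "attention_dim",
        "n_labels", "max_note_tokens", "epochs", "batch_size", "learning_rate",
        "decision_threshold", "early_stop_patience", "seed",
    },
    "attack": {"attack_models", "balance", "n_folds", "seed", "multilabel"},
    "sweep": {
        "training_set_sizes", "max_note_tokens_values", "key_phrase_counts",
        "n_seed_replicates",
    },
}


def load_config(path: str | Path) -> RunConfig:
    """Load a YAML run configuration, applying defaults for omitted keys."""
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError(f"top level of {path} must be a mapping")

    known_sections = {f.name for f in dataclasses.fields(RunConfig)}
    for key in raw:
        if key not in known_sections:
            raise ConfigError(f"unknown config section or key: {key!r}")
    for section, keys in _KNOWN_KEYS.items():
        body = raw.get(section) or {}
        if not isinstance(body, dict):
            raise ConfigError(f"section {section!r} must be a mapping")
        for key in body:
            if key not in keys:
                raise ConfigError(f"unknown key {key!r} in section {section!r}")

    seed = raw.get("seed", 0)
    if not isinstance(seed, int):
        raise ConfigError(f"seed must be an integer, got {seed!r}")
    return RunConfig(
        seed=seed,
        **{s: dict(raw.get(s) or {}) for s in _KNOWN_KEYS},
    )
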