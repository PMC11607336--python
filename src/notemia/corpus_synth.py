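"""Seeded synthetic clinical corpus with code-conditional signal.

Real discharge summaries carry diagnosis-specific language mixed into large
amounts of boilerplate.  This module emulates exactly the statistical
structure the rest of the pipeline relies on, without any real patient data:

* a label space of ``n_codes`` diagnosis codes with a skewed (Zipf-like)
  prevalence profile, the most frequent codes dominating;
* per-code *signature phrases* — short multi-token phrases unique to one
  code — embedded in background filler at a configurable injection rate
  (the learnability knob: rate 1.0 makes the coding task easy, rate 0.0
  removes all code/text signal);
* configurable note length, disjoint train/validation/test splits, and
  optional PHI surrogate tokens with an exact scrubber.

PHI surrogates use a reserved bracketed token class (``[**PHI-NAME-3**]``),
mirroring the bracketed placeholders of de-identified hospital corpora, so
that scrubbing is exact and testable.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace

import numpy as np

from notemia._words import FILLER_WORDS, SIGNATURE_LEXICON
from notemia.errors import ValidationError

__all__ = [
    "CodeSpec",
    "CorpusConfig",
    "Note",
    "PHI_TOKEN_PATTERN",
    "build_code_universe",
    "generate_corpus",
    "inject_phi",
    "scrub_phi",
]

#: Exact pattern of a PHI surrogate token (always a single whitespace token).
PHI_TOKEN_PATTERN = re.compile(r"\[\*\*PHI-[A-Z]+\*\*\]")

_PHI_CATEGORIES = ("NAME", "DATE", "LOCATION", "ID")


@dataclass(frozen=True)
class CodeSpec:
    """One diagnosis code: identifier, prevalence weight, signature phrases."""

    code: str
    prevalence: float
    signature_phrases: tuple[str, ...]

    def __post_init__(self):
        if not 0 < self.prevalence <= 1:
            raise ValidationError(f"prevalence must be in (0,1]: {self.prevalence}")


@dataclass(frozen=True)
class CorpusConfig:
    """Knobs of the synthetic corpus generator."""

    n_notes: int = 500
    n_codes: int = 50
    mean_codes_per_note: float = 3.0
    note_length_tokens: tuple[int, int] = (50, 120)
    signature_injection_rate: float = 1.0
    phi_rate: float = 0.0
    split_fractions: tuple[float, float, float] = (0.7, 0.1, 0.2)
    seed: int = 0

    def __post_init__(self):
        if self.n_notes < 1 or self.n_codes < 1:
            raise ValidationError("n_notes and n_codes must be positive")
        lo, hi = self.note_length_tokens
        if lo > hi or lo < 1:
            raise ValidationError(f"invalid note_length_tokens: {(lo, hi)}")
        if not 0 <= self.signature_injection_rate <= 1:
            raise ValidationError("signature_injection_rate must be in [0,1]")
        if self.phi_rate < 0:
            raise ValidationError("phi_rate must be >= 0")
        fr = self.split_fractions
        if len(fr) != 3 or any(not 0 < f < 1 for f in fr) or abs(sum(fr) - 1) > 1e-9:
            raise ValidationError(f"split fractions must be in (0,1) and sum to 1: {fr}")


@dataclass(frozen=True)
class Note:
    """A clinical-note record: id, free text, label codes, split."""

    note_id: str
    text: str
    codes: frozenset[str] = field(default_factory=frozenset)
    split: str = "train"

    def __post_init__(self):
        if self.split not in ("train", "val", "test"):
            raise ValidationError(f"unknown split: {self.split!r}")
        if not self.text:
            raise ValidationError(f"note {self.note_id!r} has empty text")


def build_code_universe(
    n_codes: int = 50, phrases_per_code: int = 3, seed: int = 0
) -> list[CodeSpec]:
    """Build a label universe with Zipf-like prevalence and unique signatures.

    Prevalence of the rank-``r`` code is proportional to ``1/(r+1)`` and
    normalized to sum to one over the universe.  Each code receives
    ``phrases_per_code`` three-token signature phrases assembled from a
    pseudo-clinical lexicon; no word, and hence no phrase, is shared between
    two codes while the lexicon lasts.
    """
    if n_codes < 1:
        raise ValidationError(f"n_codes must be >= 1, got {n_codes}")
    if phrases_per_code < 1:
        raise ValidationError(f"phrases_per_code must be >= 1, got {phrases_per_code}")

    rng = np.random.default_rng(seed)
    weights = 1.0 / (np.arange(n_codes) + 1.0)
    weights /= weights.sum()

    n_words = n_codes * phrases_per_code * 3
    lexicon = list(SIGNATURE_LEXICON)
    rng.shuffle(lexicon)
    if n_words <= len(lexicon):
        pool = lexicon[:n_words]
    else:  # lexicon exhausted: reuse words but keep phrase tuples unique
        reps = math.ceil(n_words / len(lexicon))
        pool = (lexicon * reps)[:n_words]

    universe: list[CodeSpec] = []
    seen_phrases: set[str] = set()
    cursor = 0
    for i in range(n_codes):
        phrases = []
        for _ in range(phrases_per_code):
            phrase = " ".join(pool[cursor : cursor + 3])
            cursor += 3
            while phrase in seen_phrases:  # only reachable when words repeat
                extra = lexicon[int(rng.integers(len(lexicon)))]
                phrase = phrase + " " + extra
            seen_phrases.add(phrase)
            phrases.append(phrase)
        universe.append(
            CodeSpec(
                code=f"dx_{i + 1:03d}",
                prevalence=float(weights[i]),
                signature_phrases=tuple(phrases),
            )
        )
    return universe


def _split_counts(n: int, fractions: tuple[float, float, float]) -> tuple[int, int, int]:
    """Largest-remainder apportionment of n notes over (train, val, test)."""
    raw = [n * f for f in fractions]
    counts = [int(math.floor(x)) for x in raw]
    remainders = sorted(range(3), key=lambda i: raw[i] - counts[i], reverse=True)
    for i in range(n - sum(counts)):
        counts[remainders[i % 3]] += 1
    return tuple(counts)  # type: ignore[return-value]


def _sample_codes(universe, rates, rng) -> frozenset[str]:
    # Per-code independent Bernoulli; resample if empty so every note is
    # labelled without distorting the marginals much.
    while True:
        mask = rng.random(len(universe)) < rates
        if mask.any():
            return frozenset(spec.code for spec, m in zip(universe, mask) if m)


def _filler_sentence_tokens(n: int, rng) -> list[str]:
    """n filler tokens grouped into sentences (periods attach to last word)."""
    idx = rng.integers(0, len(FILLER_WORDS), size=n)
    tokens = [FILLER_WORDS[i] for i in idx]
    pos = 0
    while pos < n:
        pos += int(rng.integers(6, 13))
        end = min(pos, n) - 1
        tokens[end] = tokens[end] + "."
    return tokens


def generate_corpus(universe: list[CodeSpec], config: CorpusConfig) -> list[Note]:
    """Generate a full corpus of labelled notes; deterministic given seed.

    Each note draws its label set by prevalence-proportional Bernoulli
    sampling (mean cardinality ≈ ``mean_codes_per_note``), then builds its
    text as filler sentences with signature phrases of its assigned codes
    spliced in at sentence-internal token boundaries.  Injected phrases
    occur once or twice, so genuine signal outranks one-off filler n-grams
    in frequency-based phrase extraction, as diagnosis language does in
    real notes.
    """
    if not universe:
        raise ValidationError("universe must not be empty")
    if config.n_codes != len(universe):
        raise ValidationError(
            f"config.n_codes={config.n_codes} != |universe|={len(universe)}"
        )
    rng = np.random.default_rng(config.seed)

    prevalence = np.array([s.prevalence for s in universe])
    prevalence = prevalence / prevalence.sum()
    rates = np.clip(prevalence * config.mean_codes_per_note, 0.0, 0.95)

    counts = _split_counts(config.n_notes, config.split_fractions)
    split_of = np.repeat(["train", "val", "test"], counts)
    rng.shuffle(split_of)

    by_code = {s.code: s for s in universe}
    lo, hi = config.note_length_tokens
    notes: list[Note] = []
    for i in range(config.n_notes):
        codes = _sample_codes(universe, rates, rng)
        target_len = int(rng.integers(lo, hi + 1))

        injected: list[list[str]] = []
        for code in sorted(codes):
            for phrase in by_code[code].signature_phrases:
                if rng.random() < config.signature_injection_rate:
                    for _ in range(1 + int(rng.random() < 0.5)):
                        injected.append(phrase.split())

        n_injected = sum(len(p) for p in injected)
        n_filler = max(target_len - n_injected, 8)
        tokens = _filler_sentence_tokens(n_filler, rng)

        # Splice phrase blocks between filler tokens; sentence punctuation is
        # attached to filler words, so a phrase never straddles a boundary.
        order = rng.permutation(len(injected))
        positions = sorted(
            (int(rng.integers(0, len(tokens) + 1)) for _ in injected), reverse=True
        )
        for pos, j in zip(positions, order):
            tokens[pos:pos] = injected[j]

        note = Note(
            note_id=f"note-{i:05d}",
            text=" ".join(tokens),
            codes=codes,
            split=str(split_of[i]),
        )
        if config.phi_rate > 0:
            note = inject_phi(note, config.phi_rate, rng)
        notes.append(note)
    return notes


def inject_phi(
    note: Note,
    phi_rate: float,
    rng: np.random.Generator,
    placement: str = "header",
) -> Note:
    """Insert PHI surrogate tokens (Poisson-many with mean ``phi_rate``).

    Surrogates are generic category placeholders (``[**PHI-NAME**]``,
    ``[**PHI-DATE**]``, ...), mirroring de-identified hospital corpora
    where placeholders carry no patient-specific content.

    ``placement="header"`` (default) puts them in a block at the start of
    the note, like the demographic front matter of a discharge summary.
    In real notes, placeholder positions are anchored to the surrounding
    narrative; sampling positions independently at random would instead
    stamp each note with an information-free but note-specific placement
    fingerprint that a memorizing model can exploit — an identification
    channel real de-identified text does not carry.  ``placement="random"``
    provides exactly that behaviour for studying the channel: positions
    drawn uniformly over sentence boundaries (so embedded signature
    phrases are never split).
    """
    if phi_rate < 0:
        raise ValidationError("phi_rate must be >= 0")
    if placement not in ("header", "random"):
        raise ValidationError(f"unknown placement: {placement!r}")
    count = int(rng.poisson(phi_rate))
    if count == 0:
        return note
    tokens = note.text.split()
    cats = [
        _PHI_CATEGORIES[int(rng.integers(len(_PHI_CATEGORIES)))]
        for _ in range(count)
    ]
    if placement == "header":
        draws = [(0, cat) for cat in cats]
    else:
        boundaries = [0] + [i + 1 for i, t in enumerate(tokens) if t.endswith(".")]
        draws = [
            (boundaries[int(rng.integers(len(boundaries)))], cat) for cat in cats
        ]
    # Insert back-to-front so earlier insertions cannot shift later targets
    # into the middle of a phrase.
    for pos, cat in sorted(draws, key=lambda d: d[0], reverse=True):
        tokens.insert(pos, f"[**PHI-{cat}**]")
    return replace(note, text=" ".join(tokens))


def scrub_phi(note: Note) -> Note:
    """Remove every PHI surrogate token; all other tokens keep their order.

    Exact and idempotent by construction of the sentinel token class.
    """
    kept = [t for t in note.text.split() if not PHI_TOKEN_PATTERN.fullmatch(t)]
    return replace(note, text=" ".join(kept))
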