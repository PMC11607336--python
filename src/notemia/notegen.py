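"""Prompt construction and synthetic note generation.

A synthetic note is produced by instructing a text-generation backend to
write a patient description that contains an ordered list of key phrases
("sequentially"), so the clinical content of the source note is preserved
while the surrounding language is re-written.  Two prompt wordings are
supported (``v0301`` and ``v0613``, matching two snapshot styles of the
instruction), both with a configurable word budget (default 2250 words
against a completion cap of 3000 tokens).

The backend is a contract (:class:`GenerationBackend`); the bundled
:class:`StubBackend` is a deterministic offline implementation that embeds
every phrase, in order, inside seeded connective sentences — it makes the
whole pipeline runnable and testable without credentials or network.
Token budgets are enforced on whitespace tokens (a documented proxy for
model-tokenizer counts).
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, replace
from typing import Protocol, runtime_checkable

import numpy as np

from notemia._seeding import child_seed
from notemia._words import FILLER_WORDS, STUB_CLOSERS, STUB_FILLER, STUB_OPENERS
from notemia.corpus_synth import Note
from notemia.errors import GenerationError, ValidationError
from notemia.keyphrase import ExtractorConfig, extract_keyphrases, preprocess_note

__all__ = [
    "Prompt",
    "GenerationBackend",
    "StubBackend",
    "PROMPT_TEMPLATES",
    "build_prompt",
    "generate_note",
    "stub_generate",
    "phrase_coverage",
    "synthesize_corpus",
]

PROMPT_TEMPLATES = {
    "v0301": (
        "Write a description of a patient using {budget} words containing "
        "the following phrases sequentially:"
    ),
    "v0613": (
        "Write a description of a patient using {budget} words. The "
        "description should contain the following phrases sequentially:"
    ),
}


@dataclass(frozen=True)
class Prompt:
    """An instruction plus the ordered phrase list it carries."""

    instruction: str
    phrases: tuple[str, ...]
    variant: str
    word_budget: int = 2250


@runtime_checkable
class GenerationBackend(Protocol):
    """Contract for note-generating backends."""

    deterministic: bool

    def generate(
        self, prompt: Prompt, max_completion_tokens: int, seed: int | None = None
    ) -> str:
        ...


def build_prompt(
    phrases: list[str], variant: str = "v0613", word_budget: int = 2250
) -> Prompt:
    """Assemble the instruction for one note from its ordered phrases."""
    if not phrases:
        raise ValidationError("phrase list must not be empty")
    if variant not in PROMPT_TEMPLATES:
        raise ValidationError(
            f"unknown prompt variant {variant!r}; expected one of "
            f"{sorted(PROMPT_TEMPLATES)}"
        )
    instruction = PROMPT_TEMPLATES[variant].format(budget=word_budget)
    instruction = instruction + " " + ", ".join(phrases)
    return Prompt(
        instruction=instruction,
        phrases=tuple(phrases),
        variant=variant,
        word_budget=word_budget,
    )


def stub_generate(prompt: Prompt, seed: int | None = None) -> str:
    """Deterministic offline generation.

    Each phrase is wrapped, in prompt order, in a seeded connective
    sentence; filler varies with the seed but phrase tokens are never
    altered, so in-order phrase coverage is 1.0 by construction whenever
    the token budget allows.
    """
    return StubBackend().generate(prompt, max_completion_tokens=3000, seed=seed)


class StubBackend:
    """Offline deterministic generation backend (see :func:`stub_generate`)."""

    backend_id = "stub"
    deterministic = True

    def generate(
        self, prompt: Prompt, max_completion_tokens: int, seed: int | None = None
    ) -> str:
        rng = np.random.default_rng(0 if seed is None else seed)
        budget = max_completion_tokens
        tokens: list[str] = []

        def connective(n_lo: int, n_hi: int) -> list[str]:
            # Connective text shares the clinical background vocabulary, as
            # a fluent in-domain generator would; the seed varies it.
            n = int(rng.integers(n_lo, n_hi + 1))
            return [
                FILLER_WORDS[int(rng.integers(len(FILLER_WORDS)))] for _ in range(n)
            ]

        for phrase in prompt.phrases:
            phrase_tokens = phrase.split()
            if rng.random() < 0.3:
                opener = STUB_OPENERS[int(rng.integers(len(STUB_OPENERS)))].split()
            else:
                opener = connective(1, 3)
            if rng.random() < 0.3:
                closer = STUB_CLOSERS[int(rng.integers(len(STUB_CLOSERS)))].split()
            else:
                closer = connective(1, 3)
            sentence = opener + phrase_tokens + closer
            if rng.random() < 0.3:
                sentence = [STUB_FILLER[int(rng.integers(len(STUB_FILLER)))]] + sentence
            if budget - len(sentence) < 0:
                # Degrade gracefully: drop connectives before dropping phrases.
                sentence = phrase_tokens
                if budget - len(sentence) < 0:
                    break
            sentence = sentence[:-1] + [sentence[-1] + "."]
            tokens.extend(sentence)
            budget -= len(sentence)
        if not tokens:
            tokens = ["patient", "description", "unavailable."]
        return " ".join(tokens)


def generate_note(
    backend: GenerationBackend,
    prompt: Prompt,
    max_completion_tokens: int = 3000,
    seed: int | None = None,
    log: list[dict] | None = None,
) -> str:
    """Generate one note through the backend, recording the call.

    Backend failures surface as :class:`GenerationError` carrying the
    original diagnostics (retriable by the caller).
    """
    try:
        text = backend.generate(prompt, max_completion_tokens, seed=seed)
    except Exception as exc:  # noqa: BLE001 — backend contract boundary
        raise GenerationError(f"backend failed: {exc}") from exc
    if log is not None:
        log.append(
            {
                "backend": getattr(backend, "backend_id", type(backend).__name__),
                "variant": prompt.variant,
                "n_phrases": len(prompt.phrases),
                "prompt_tokens": len(prompt.instruction.split()),
                "completion_tokens": len(text.split()),
                "seed": seed,
            }
        )
    return text


def phrase_coverage(text: str, phrases: list[str]) -> tuple[float, float]:
    """How many prompt phrases the text contains, and how many in order.

    ``present_fraction`` counts verbatim substring hits.
    ``in_order_fraction`` is the length of the longest strictly increasing
    subsequence of first-match offsets, divided by the number of phrases.
    """
    if not phrases:
        return 1.0, 1.0
    offsets = [text.find(p) for p in phrases]
    present = [o for o in offsets if o >= 0]
    # O(n log n) longest strictly increasing subsequence.
    tails: list[int] = []
    for off in present:
        pos = bisect.bisect_left(tails, off)
        if pos == len(tails):
            tails.append(off)
        else:
            tails[pos] = off
    n = len(phrases)
    return len(present) / n, len(tails) / n


def synthesize_corpus(
    notes: list[Note],
    extractor_config: ExtractorConfig,
    backend: GenerationBackend,
    variant: str = "v0613",
    seed: int = 0,
    max_completion_tokens: int = 3000,
    word_budget: int = 2250,
    retries: int = 2,
    log: list[dict] | None = None,
) -> list[Note]:
    """Replace every note's text with a synthetic counterpart.

    Note ids, label sets and split assignments are preserved — only the
    text changes — so utility evaluation against the real test labels and
    the membership pairing against real notes remain well-defined.  Failed
    generations are retried, then fall back to the stub backend and are
    flagged in the log.
    """
    fallback = StubBackend()
    out: list[Note] = []
    for note in notes:
        phrases = [
            p.text for p in extract_keyphrases(note.text, extractor_config)
        ]
        if not phrases:  # degenerate note (e.g. all stopwords)
            phrases = [preprocess_note(note.text).split()[0] or "patient"]
        prompt = build_prompt(phrases, variant=variant, word_budget=word_budget)
        note_seed = child_seed(seed, f"notegen:{note.note_id}")
        text = None
        for _attempt in range(retries + 1):
            try:
                text = generate_note(
                    backend, prompt, max_completion_tokens, seed=note_seed, log=log
                )
                break
            except GenerationError:
                continue
        if text is None:
            text = generate_note(
                fallback, prompt, max_completion_tokens, seed=note_seed, log=log
            )
            if log is not None:
                log.append({"flagged_fallback": note.note_id})
        out.append(replace(note, text=text))
    return out
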