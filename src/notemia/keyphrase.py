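"""Unsupervised key-phrase extraction for prompt construction.

The extraction stage turns a clinical note into a short, ordered sequence of
informative phrases.  Two complementary statistical scorers are run:

* :func:`score_frequency_position` — rewards frequent candidates that appear
  early in the document, with a multiplicative boost for multi-token
  phrases (the frequency/position/multiword family of keyword extractors);
* :func:`score_multifeature` — combines per-term position, normalized
  frequency and sentence dispersion into a multiplicative "badness" that is
  low for good terms (the multi-statistic family; scores are negated so
  that larger = more relevant holds module-wide).

Both outputs are fuzzily de-duplicated and merged, then ordered by place of
first appearance in the note — the order in which the phrases will be handed
to the generation prompt.

Conventions (deterministic and testable): token = whitespace unit;
punctuation characters ``. ! ? , ; :`` are split into standalone tokens
during preprocessing; sentence boundaries are ``.``, ``!``, ``?`` and
newline; ties everywhere break by (first offset, lexicographic).
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, replace

import edlib

from difflib import SequenceMatcher

from notemia.errors import NotemiaError, ValidationError

__all__ = [
    "CandidatePhrase",
    "KeyPhrase",
    "ExtractorConfig",
    "DocStats",
    "preprocess_note",
    "extract_candidates",
    "document_stats",
    "score_frequency_position",
    "score_multifeature",
    "dedup_phrases",
    "merge_and_order",
    "extract_keyphrases",
]

STOPWORDS = frozenset(
    "a an and are as at be but by for from had has have he her his i in into is it "
    "its no not of on or she that the their there these they this to was were will "
    "with without which while when where who whom".split()
)

_SENTENCE_ENDERS = frozenset({".", "!", "?"})
_PUNCT_PAD = re.compile(r"([.!?,;:])")
_NUMERIC_TOKEN = re.compile(r"[^A-Za-z]*\d[^A-Za-z]*$")  # digits, no letters


@dataclass(frozen=True)
class CandidatePhrase:
    """An n-gram candidate with exact corpus statistics."""

    tokens: tuple[str, ...]
    term_freq: int
    first_offset: int
    sentence_ids: frozenset[int]

    @property
    def text(self) -> str:
        return " ".join(self.tokens)


@dataclass(frozen=True)
class KeyPhrase:
    """A scored, ranked phrase; larger score = more relevant."""

    text: str
    score: float
    rank: int
    first_offset: int


@dataclass(frozen=True)
class ExtractorConfig:
    """Extraction parameters.

    ``lasf`` (least allowable seen frequency) filters rare candidates from
    the frequency-position scorer; ``dedup_threshold`` is the similarity
    ratio above which a lower-ranked phrase is discarded;
    ``multiword_boost`` is the per-extra-token score multiplier of the
    frequency-position scorer.
    """

    max_ngram: int = 3
    lasf: int = 1
    dedup_threshold: float = 0.70
    top_n: int = 20
    multiword_boost: float = 2.0

    def __post_init__(self):
        if self.lasf < 1:
            raise ValidationError(f"lasf must be >= 1, got {self.lasf}")
        if not 0 < self.dedup_threshold <= 1:
            raise ValidationError(
                f"dedup_threshold must be in (0,1], got {self.dedup_threshold}"
            )
        if self.max_ngram < 1 or self.top_n < 1:
            raise ValidationError("max_ngram and top_n must be positive")
        if self.multiword_boost <= 1:
            raise ValidationError("multiword_boost must be > 1")


def preprocess_note(text: str) -> str:
    """Lowercase, drop numeric tokens, separate punctuation, collapse spaces.

    Numeric tokens (digits, possibly mixed with punctuation but with no
    letters) are removed entirely; newlines become sentence boundaries.
    Idempotent.
    """
    text = text.lower().replace("\n", " . ")
    text = _PUNCT_PAD.sub(r" \1 ", text)
    kept = [t for t in text.split() if not _NUMERIC_TOKEN.fullmatch(t)]
    return " ".join(kept)


def _tokenize_with_offsets(text: str) -> list[tuple[str, int]]:
    return [(m.group(), m.start()) for m in re.finditer(r"\S+", text)]


def _is_punct(token: str) -> bool:
    return not any(ch.isalnum() for ch in token)


def extract_candidates(text: str, config: ExtractorConfig) -> list[CandidatePhrase]:
    """Enumerate all 1..max_ngram-grams that respect boundary rules.

    A candidate never crosses a punctuation token (hence never a sentence
    boundary) and never begins or ends with a stopword.  ``term_freq``,
    ``first_offset`` (character index of the first occurrence) and
    ``sentence_ids`` are exact.
    """
    tokens = _tokenize_with_offsets(text)

    # Segment at punctuation tokens; sentence index advances at enders only.
    segments: list[tuple[int, list[tuple[str, int]]]] = []
    sentence_id = 0
    current: list[tuple[str, int]] = []
    for tok, off in tokens:
        if _is_punct(tok):
            if current:
                segments.append((sentence_id, current))
                current = []
            if tok in _SENTENCE_ENDERS:
                sentence_id += 1
        else:
            current.append((tok, off))
    if current:
        segments.append((sentence_id, current))

    found: dict[tuple[str, ...], dict] = {}
    for sent_id, segment in segments:
        words = [t for t, _ in segment]
        offsets = [o for _, o in segment]
        for n in range(1, config.max_ngram + 1):
            for i in range(len(words) - n + 1):
                gram = tuple(words[i : i + n])
                if gram[0] in STOPWORDS or gram[-1] in STOPWORDS:
                    continue
                entry = found.setdefault(
                    gram,
                    {"freq": 0, "offset": offsets[i], "sentences": set()},
                )
                entry["freq"] += 1
                entry["offset"] = min(entry["offset"], offsets[i])
                entry["sentences"].add(sent_id)

    return [
        CandidatePhrase(
            tokens=gram,
            term_freq=entry["freq"],
            first_offset=entry["offset"],
            sentence_ids=frozenset(entry["sentences"]),
        )
        for gram, entry in found.items()
    ]


@dataclass(frozen=True)
class DocStats:
    """Document-level statistics shared by the scorers."""

    doc_length: int                       # characters in preprocessed text
    n_sentences: int
    term_freq: dict[str, int]             # per unigram term
    term_sentences: dict[str, frozenset[int]]
    term_first_sentence: dict[str, int]
    max_term_freq: int


def document_stats(text: str) -> DocStats:
    """Exact per-term statistics of a preprocessed document."""
    tokens = _tokenize_with_offsets(text)
    sentence_id = 0
    tf: dict[str, int] = {}
    sents: dict[str, set[int]] = {}
    first_sent: dict[str, int] = {}
    for tok, _ in tokens:
        if _is_punct(tok):
            if tok in _SENTENCE_ENDERS:
                sentence_id += 1
            continue
        tf[tok] = tf.get(tok, 0) + 1
        sents.setdefault(tok, set()).add(sentence_id)
        first_sent.setdefault(tok, sentence_id)
    return DocStats(
        doc_length=max(len(text), 1),
        n_sentences=max(sentence_id + 1, 1),
        term_freq=tf,
        term_sentences={w: frozenset(s) for w, s in sents.items()},
        term_first_sentence=first_sent,
        max_term_freq=max(tf.values(), default=1),
    )


def _ranked(scored: list[tuple[float, CandidatePhrase]]) -> list[KeyPhrase]:
    """Descending score; ties by earlier first offset, then lexicographic."""
    ordered = sorted(scored, key=lambda sc: (-sc[0], sc[1].first_offset, sc[1].text))
    return [
        KeyPhrase(text=c.text, score=s, rank=r, first_offset=c.first_offset)
        for r, (s, c) in enumerate(ordered, start=1)
    ]


def score_frequency_position(
    candidates: list[CandidatePhrase], doc_stats: DocStats, config: ExtractorConfig
) -> list[KeyPhrase]:
    """Frequency × position × multi-word boost scoring.

    ``score = tf × 1/(1 + first_offset/doc_length) × B^(n_tokens − 1)``;
    candidates seen fewer than ``lasf`` times are removed first.
    """
    scored = []
    for cand in candidates:
        if cand.term_freq < config.lasf:
            continue
        position_factor = 1.0 / (1.0 + cand.first_offset / doc_stats.doc_length)
        boost = config.multiword_boost ** (len(cand.tokens) - 1)
        scored.append((cand.term_freq * position_factor * boost, cand))
    return _ranked(scored)


def score_multifeature(
    candidates: list[CandidatePhrase], doc_stats: DocStats, config: ExtractorConfig
) -> list[KeyPhrase]:
    """Multi-statistic scoring via per-term badness.

    Per term ``w``: badness(w) = position / (freq_norm × (1 + dispersion)),
    with position = log2(2 + first sentence index of w), freq_norm =
    tf(w)/max_tf, dispersion = |sentences containing w| / n_sentences.
    Phrase badness = Π badness(w) / (tf(phrase) × (1 + Σ badness(w)));
    the exposed score is the negated badness so larger = more relevant.
    """
    scored = []
    for cand in candidates:
        prod, total = 1.0, 0.0
        for term in cand.tokens:
            position = math.log2(2 + doc_stats.term_first_sentence.get(term, 0))
            freq_norm = doc_stats.term_freq.get(term, 1) / doc_stats.max_term_freq
            dispersion = (
                len(doc_stats.term_sentences.get(term, ())) / doc_stats.n_sentences
            )
            badness = position / (freq_norm * (1.0 + dispersion))
            prod *= badness
            total += badness
        phrase_badness = prod / (cand.term_freq * (1.0 + total))
        scored.append((-phrase_badness, cand))
    return _ranked(scored)


def similarity_ratio(a: str, b: str, method: str = "block_ratio") -> float:
    """Similarity in [0, 1] between two phrase strings.

    ``block_ratio`` — longest-matching-blocks ratio (sequence matcher);
    ``edit_ratio`` — ``(|a| + |b| − edit_distance) / (|a| + |b|)``.
    """
    if method == "block_ratio":
        return SequenceMatcher(None, a, b).ratio()
    if method == "edit_ratio":
        if not a and not b:
            return 1.0
        dist = edlib.align(a, b, task="distance")["editDistance"]
        return (len(a) + len(b) - dist) / (len(a) + len(b))
    raise ValidationError(f"unknown dedup method: {method!r}")


def dedup_phrases(
    phrases: list[KeyPhrase], method: str = "block_ratio", threshold: float = 0.70
) -> list[KeyPhrase]:
    """Greedy rank-order de-duplication.

    Scanning from best rank, a phrase is dropped when its similarity ratio
    to any retained phrase reaches the threshold.  Ranks are re-assigned
    contiguously; scores are untouched.  Idempotent and order-stable.
    """
    if not 0 < threshold <= 1:
        raise ValidationError(f"threshold must be in (0,1], got {threshold}")
    kept: list[KeyPhrase] = []
    for phrase in sorted(phrases, key=lambda p: p.rank):
        if any(
            similarity_ratio(phrase.text, other.text, method) >= threshold
            for other in kept
        ):
            continue
        kept.append(phrase)
    return [replace(p, rank=r) for r, p in enumerate(kept, start=1)]


def merge_and_order(
    list_a: list[KeyPhrase],
    list_b: list[KeyPhrase],
    note_text: str,
    top_n: int,
    dedup_threshold: float = 0.70,
) -> list[KeyPhrase]:
    """Merge two extractors' outputs into the prompt phrase sequence.

    Top ⌈top_n/2⌉ phrases by rank come from ``list_a`` (the
    frequency-position extractor, which also takes the odd remainder) and
    top ⌊top_n/2⌋ from ``list_b``; the union is de-duplicated by edit
    ratio, sorted by place of first appearance in the note, and truncated
    to ``top_n``.
    """
    n_a = math.ceil(top_n / 2)
    n_b = top_n - n_a
    picked: list[KeyPhrase] = []
    seen: set[str] = set()
    for source, limit in ((list_a, n_a), (list_b, n_b)):
        for phrase in sorted(source, key=lambda p: p.rank)[:limit]:
            if phrase.text not in seen:
                seen.add(phrase.text)
                picked.append(phrase)

    merged = dedup_phrases(
        [replace(p, rank=r) for r, p in enumerate(picked, start=1)],
        method="edit_ratio",
        threshold=dedup_threshold,
    )

    located = []
    for phrase in merged:
        offset = note_text.find(phrase.text)
        if offset < 0:
            raise NotemiaError(
                f"phrase {phrase.text!r} not found in note text "
                "(extraction contract violated)"
            )
        located.append((offset, phrase))
    located.sort(key=lambda op: (op[0], op[1].text))
    return [
        replace(p, rank=r, first_offset=off)
        for r, (off, p) in enumerate(located[:top_n], start=1)
    ]


def extract_keyphrases(text: str, config: ExtractorConfig) -> list[KeyPhrase]:
    """Full pipeline for one note: preprocess, score twice, merge, order."""
    clean = preprocess_note(text)
    candidates = extract_candidates(clean, config)
    stats = document_stats(clean)
    by_freq_pos = score_frequency_position(candidates, stats, config)
    by_multifeature = score_multifeature(candidates, stats, config)
    return merge_and_order(
        by_freq_pos, by_multifeature, clean, config.top_n, config.dedup_threshold
    )
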