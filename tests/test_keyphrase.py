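import math

import pytest

from oracles import edit_distance, ngrams_oracle

from notemia import keyphrase as kp
from notemia.errors import NotemiaError, ValidationError


class TestPreprocess:
    @pytest.mark.parametrize(
        "raw,expected",
        [
            ("Pt admitted 2019 with CHF", "pt admitted with chf"),
            ("", ""),
            ("Dose 12.5 given", "dose . given"),
            ("fever,  chills", "fever , chills"),
            ("line one\nline two", "line one . line two"),
        ],
    )
    def test_examples(self, raw, expected):
        assert kp.preprocess_note(raw) == expected

    def test_idempotent(self, signature_corpus):
        for note in signature_corpus[:20]:
            once = kp.preprocess_note(note.text)
            assert kp.preprocess_note(once) == once


class TestCandidates:
    def test_matches_bruteforce_enumeration(self, signature_corpus):
        config = kp.ExtractorConfig(max_ngram=3)
        for note in signature_corpus[:10]:
            text = kp.preprocess_note(note.text)
            candidates = kp.extract_candidates(text, config)
            expected = ngrams_oracle(text, 3, kp.STOPWORDS)
            got = {c.tokens: (c.term_freq, c.first_offset) for c in candidates}
            assert got == expected

    def test_trigram_and_subgrams_present(self):
        text = "acute renal failure"
        grams = {c.text for c in kp.extract_candidates(text, kp.ExtractorConfig())}
        assert {"acute renal failure", "acute renal", "renal failure",
                "acute", "renal", "failure"} <= grams

    def test_empty_text_gives_no_candidates(self):
        assert kp.extract_candidates("", kp.ExtractorConfig()) == []

    def test_offsets_are_token_aligned_first_occurrences(self, signature_corpus):
        config = kp.ExtractorConfig()
        text = kp.preprocess_note(signature_corpus[0].text)
        for cand in kp.extract_candidates(text, config):
            off = cand.first_offset
            assert text[off : off + len(cand.text)] == cand.text
            assert off == 0 or text[off - 1] == " "


def _cand(tokens, freq, offset, sentences=(0,)):
    return kp.CandidatePhrase(
        tokens=tuple(tokens), term_freq=freq, first_offset=offset,
        sentence_ids=frozenset(sentences),
    )


class TestFrequencyPositionScorer:
    def test_lasf_filters_rare_candidates(self):
        stats = kp.DocStats(100, 1, {}, {}, {}, 1)
        config = kp.ExtractorConfig(lasf=2)
        ranked = kp.score_frequency_position(
            [_cand(["rare"], 1, 0), _cand(["common"], 2, 10)], stats, config
        )
        assert [p.text for p in ranked] == ["common"]
        assert ranked[0].rank == 1

    def test_multiword_boost_doubles_bigram_score(self):
        # equal frequency and offset: bigram beats unigram by exactly B=2
        stats = kp.DocStats(200, 1, {}, {}, {}, 2)
        config = kp.ExtractorConfig()
        ranked = kp.score_frequency_position(
            [_cand(["alpha"], 2, 0), _cand(["beta", "gamma"], 2, 0)], stats, config
        )
        assert [p.text for p in ranked] == ["beta gamma", "alpha"]
        assert ranked[0].score == pytest.approx(2 * ranked[1].score)

    def test_position_factor_prefers_earlier_phrase(self):
        stats = kp.DocStats(100, 1, {}, {}, {}, 1)
        ranked = kp.score_frequency_position(
            [_cand(["late"], 1, 90), _cand(["early"], 1, 0)],
            stats, kp.ExtractorConfig(),
        )
        assert [p.text for p in ranked] == ["early", "late"]
        assert ranked[0].score == pytest.approx(1.0)
        assert ranked[1].score == pytest.approx(1 / 1.9)


class TestMultiFeatureScorer:
    def test_dispersed_term_ranks_higher(self):
        stats = kp.DocStats(
            doc_length=100, n_sentences=3,
            term_freq={"x": 3, "y": 3},
            term_sentences={"x": frozenset({0, 1, 2}), "y": frozenset({0})},
            term_first_sentence={"x": 0, "y": 0},
            max_term_freq=3,
        )
        ranked = kp.score_multifeature(
            [_cand(["x"], 3, 0), _cand(["y"], 3, 0)], stats, kp.ExtractorConfig()
        )
        assert [p.text for p in ranked] == ["x", "y"]
        # hand evaluation of the badness formula
        badness_x = 1.0 / (1.0 * (1.0 + 1.0))
        badness_y = 1.0 / (1.0 * (1.0 + 1 / 3))
        assert ranked[0].score == pytest.approx(-badness_x / (3 * (1 + badness_x)))
        assert ranked[1].score == pytest.approx(-badness_y / (3 * (1 + badness_y)))

    def test_single_candidate_gets_rank_one(self):
        stats = kp.DocStats(10, 1, {"solo": 1}, {"solo": frozenset({0})}, {"solo": 0}, 1)
        (only,) = kp.score_multifeature([_cand(["solo"], 1, 0)], stats, kp.ExtractorConfig())
        assert only.rank == 1

    def test_deterministic_on_fixed_input(self, signature_corpus):
        text = kp.preprocess_note(signature_corpus[0].text)
        config = kp.ExtractorConfig()
        candidates = kp.extract_candidates(text, config)
        stats = kp.document_stats(text)
        first = kp.score_multifeature(candidates, stats, config)
        second = kp.score_multifeature(candidates, stats, config)
        assert first == second


def _ranked_phrases(texts):
    return [
        kp.KeyPhrase(text=t, score=-r, rank=r, first_offset=0)
        for r, t in enumerate(texts, start=1)
    ]


class TestDedup:
    def test_exact_duplicates_collapse(self):
        kept = kp.dedup_phrases(_ranked_phrases(["heart failure", "heart failure"]))
        assert [p.text for p in kept] == ["heart failure"]

    def test_disjoint_strings_both_kept(self):
        kept = kp.dedup_phrases(_ranked_phrases(["abc", "xyz"]))
        assert len(kept) == 2

    def test_edit_ratio_agrees_with_reference_distance(self):
        a, b = "congestive heart failure", "heart failure"
        ratio = (len(a) + len(b) - edit_distance(a, b)) / (len(a) + len(b))
        assert kp.similarity_ratio(a, b, "edit_ratio") == pytest.approx(ratio)
        kept = kp.dedup_phrases(_ranked_phrases([a, b]), method="edit_ratio")
        expected = 1 if ratio >= 0.70 else 2
        assert len(kept) == expected

    def test_idempotent_and_order_stable(self, signature_corpus):
        config = kp.ExtractorConfig()
        text = kp.preprocess_note(signature_corpus[1].text)
        candidates = kp.extract_candidates(text, config)
        ranked = kp.score_frequency_position(candidates, kp.document_stats(text), config)
        once = kp.dedup_phrases(ranked, method="edit_ratio")
        assert kp.dedup_phrases(once, method="edit_ratio") == once
        texts = [p.text for p in once]
        original_order = [p.text for p in ranked if p.text in set(texts)]
        assert texts == original_order


class TestMergeAndOrder:
    def test_output_ordered_by_appearance(self, signature_corpus):
        config = kp.ExtractorConfig(top_n=12)
        for note in signature_corpus[:10]:
            phrases = kp.extract_keyphrases(note.text, config)
            offsets = [p.first_offset for p in phrases]
            assert offsets == sorted(offsets)
            assert [p.rank for p in phrases] == list(range(1, len(phrases) + 1))

    def test_disjoint_lists_fully_retained(self):
        note_text = "aa bb cc dd ee ff gg hh ii jj"
        list_a = [
            kp.KeyPhrase(t, -r, r, 0)
            for r, t in enumerate(["aa", "cc", "ee", "gg", "ii"], 1)
        ]
        list_b = [
            kp.KeyPhrase(t, -r, r, 0)
            for r, t in enumerate(["bb", "dd", "ff", "hh", "jj"], 1)
        ]
        merged = kp.merge_and_order(list_a, list_b, note_text, top_n=10)
        assert [p.text for p in merged] == note_text.split()

    def test_union_matches_bruteforce_oracle(self, signature_corpus):
        config = kp.ExtractorConfig(top_n=10)
        for note in signature_corpus[:6]:
            text = kp.preprocess_note(note.text)
            candidates = kp.extract_candidates(text, config)
            stats = kp.document_stats(text)
            list_a = kp.score_frequency_position(candidates, stats, config)
            list_b = kp.score_multifeature(candidates, stats, config)
            merged = kp.merge_and_order(list_a, list_b, text, top_n=10)

            # oracle: pick, unite, greedily dedup with the reference ratio
            picks = []
            for source, limit in ((list_a, 5), (list_b, 5)):
                for p in sorted(source, key=lambda q: q.rank)[:limit]:
                    if p.text not in picks:
                        picks.append(p.text)
            kept = []
            for text_p in picks:
                sims = [
                    (len(text_p) + len(q) - edit_distance(text_p, q))
                    / (len(text_p) + len(q))
                    for q in kept
                ]
                if not any(s >= 0.70 for s in sims):
                    kept.append(text_p)
            assert {p.text for p in merged} == set(kept[:10])

    def test_phrase_missing_from_note_is_a_contract_violation(self):
        ghost = [kp.KeyPhrase("not here", 1.0, 1, 0)]
        with pytest.raises(NotemiaError):
            kp.merge_and_order(ghost, [], "totally different text", top_n=5)

    def test_selection_is_monotone_in_top_n(self):
        list_a = _ranked_phrases([f"a{i}" for i in range(20)])
        list_b = _ranked_phrases([f"b{i}" for i in range(20)])
        for small, large in ((4, 8), (8, 16)):
            picks_small = list_a[: math.ceil(small / 2)] + list_b[: small // 2]
            picks_large = list_a[: math.ceil(large / 2)] + list_b[: large // 2]
            assert {p.text for p in picks_small} <= {p.text for p in picks_large}

    def test_every_phrase_occurs_verbatim_in_preprocessed_note(self, signature_corpus):
        config = kp.ExtractorConfig(top_n=16)
        for note in signature_corpus[:10]:
            clean = kp.preprocess_note(note.text)
            for phrase in kp.extract_keyphrases(note.text, config):
                assert phrase.text in clean


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs", [{"lasf": 0}, {"dedup_threshold": 0.0}, {"dedup_threshold": 1.2},
                   {"max_ngram": 0}, {"multiword_boost": 1.0}]
    )
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ValidationError):
            kp.ExtractorConfig(**kwargs)
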