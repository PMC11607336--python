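"""Extract an ordered key-phrase sequence from one note.

Two statistical scorers (frequency-position and multi-feature) are merged,
de-duplicated at ratio 0.70, and ordered by place of appearance — the
sequence that will drive the generation prompt.
"""

from notemia import corpus_synth as cs
from notemia.keyphrase import ExtractorConfig, extract_keyphrases

universe = cs.build_code_universe(n_codes=20, phrases_per_code=3, seed=1)
corpus = cs.generate_corpus(
    universe,
    cs.CorpusConfig(n_notes=10, n_codes=20, note_length_tokens=(40, 80), seed=2),
)
note = corpus[0]
print(f"note {note.note_id}, codes {sorted(note.codes)}\n")

config = ExtractorConfig(max_ngram=3, lasf=1, dedup_threshold=0.70, top_n=12)
for phrase in extract_keyphrases(note.text, config):
    print(f"  rank {phrase.rank:2d}  offset {phrase.first_offset:4d}  {phrase.text}")
# Offsets are non-decreasing: the phrases read in the order the note
# mentions them, which is what "sequentially" in the prompt relies on.
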