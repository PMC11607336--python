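"""Embedded word material for the synthetic corpus and the generation stub.

Two disjoint pools are built deterministically at import time:

* ``FILLER_WORDS`` — common function words plus generic clinical vocabulary,
  used as background text.  Includes stopwords on purpose so that key-phrase
  candidate trimming has work to do.
* ``SIGNATURE_LEXICON`` — pseudo-clinical terms assembled from Latinate
  syllables.  Signature phrases are drawn from this pool only, so a filler
  n-gram can never collide verbatim with a code's signature phrase.
"""

from __future__ import annotations

import itertools

FILLER_WORDS: tuple[str, ...] = (
    "the patient was admitted with complaints of discomfort and fatigue "
    "history of present illness reviewed on examination vital signs stable "
    "a course of treatment started and tolerated well without complication "
    "labs were drawn and results pending at this time plan to continue "
    "current regimen with close follow up as an outpatient she denied fever "
    "chills nausea or vomiting he reported mild intermittent pain improved "
    "with rest physical exam unremarkable heart regular rate and rhythm "
    "lungs clear to auscultation abdomen soft nontender no acute distress "
    "medications reconciled on admission and continued during the stay "
    "patient remained afebrile throughout hospitalization diet advanced as "
    "tolerated ambulating independently prior to discharge instructions "
    "given and understood return precautions discussed in detail condition "
    "at discharge improved disposition home with services arranged"
).split()

_ONSETS = (
    "card", "ren", "hepat", "neur", "gastr", "pulmon", "vascul", "derm",
    "oste", "my", "nephr", "arthr", "bronch", "cerebr", "col", "cyst",
    "enter", "gloss", "hem", "lymph", "mening", "ocul", "ot", "phleb",
    "pneum", "rhin", "splen", "thorac", "trache", "ven",
)
_CODAS = (
    "itis", "osis", "emia", "opathy", "ectasis", "algia", "oma", "orrhea",
    "oplasty", "ostomy", "otomy", "osclerosis", "ospasm", "ostenosis",
    "omegaly", "itis acuta", "ogram", "olysis", "oplegia", "orrhage",
    "opexy", "oscopy", "otripsy", "ocele",
)

# 30 x 24 = 720 distinct pseudo-clinical terms; multiword codas are split
# into their component tokens when phrases are assembled.
SIGNATURE_LEXICON: tuple[str, ...] = tuple(
    onset + coda.split()[0] for onset, coda in itertools.product(_ONSETS, _CODAS)
)

# Connective material for the deterministic generation stub.
STUB_OPENERS: tuple[str, ...] = (
    "the patient presented with",
    "clinical review documented",
    "assessment was notable for",
    "the record describes",
    "findings included",
    "the admission course featured",
)
STUB_CLOSERS: tuple[str, ...] = (
    "which was managed supportively",
    "and this was monitored closely",
    "with gradual improvement noted",
    "prompting further evaluation",
    "as documented by the care team",
    "and follow up was arranged",
)
STUB_FILLER: tuple[str, ...] = (
    "subsequently", "overall", "notably", "thereafter", "meanwhile",
    "accordingly", "in summary", "additionally", "furthermore", "clinically",
)
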