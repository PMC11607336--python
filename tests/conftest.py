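import warnings

import pytest

from notemia import corpus_synth as cs
from notemia import experiments as ex
from notemia import icd_classifier as ic

warnings.filterwarnings("ignore", message=".*Maximum iterations.*")
warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture(scope="session")
def universe20():
    return cs.build_code_universe(n_codes=20, phrases_per_code=3, seed=1)


@pytest.fixture(scope="session")
def signature_corpus(universe20):
    """300 notes with every signature phrase injected (fully learnable)."""
    config = cs.CorpusConfig(
        n_notes=300, n_codes=20, mean_codes_per_note=3.0,
        note_length_tokens=(40, 80), signature_injection_rate=1.0, seed=2,
    )
    return cs.generate_corpus(universe20, config)


@pytest.fixture(scope="session")
def trained_victim(universe20, signature_corpus):
    """One victim shared by classifier tests (trained once per session)."""
    train, val, _test = ex.split_corpus(signature_corpus)
    config = ic.ClassifierConfig(
        n_labels=20, max_note_tokens=96, epochs=25, seed=0
    )
    return ic.train_classifier(train, val, universe20, config)
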