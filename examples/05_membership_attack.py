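"""Audit a victim classifier with the membership-inference attack suite.

An overfit victim (100 epochs) leaks membership: its prediction vectors
for training notes are detectably more confident than for unseen notes.
"""

from notemia import corpus_synth as cs
from notemia import experiments as ex
from notemia import icd_classifier as ic
from notemia.mia_attack import AttackConfig

universe = cs.build_code_universe(n_codes=20, phrases_per_code=3, seed=1)
corpus = cs.generate_corpus(
    universe,
    cs.CorpusConfig(
        n_notes=400, n_codes=20, note_length_tokens=(40, 80),
        signature_injection_rate=0.6, split_fractions=(0.45, 0.1, 0.45), seed=2,
    ),
)

for epochs in (5, 100):
    config = ic.ClassifierConfig(n_labels=20, max_note_tokens=96,
                                 epochs=epochs, seed=0)
    utility, attack = ex.run_real_experiment(
        corpus, universe, config, AttackConfig(seed=0)
    )
    best = attack.metrics[attack.best_model]
    print(f"epochs={epochs:3d}: test micro-F1 {utility.micro_f1:.3f} | "
          f"best attacker {attack.best_model} "
          f"advantage {best.advantage:.3f}, AUC {best.auc:.3f}")
# Advantage 0 means the attacker cannot beat guessing; it grows with the
# victim's generalization gap, which is the leakage the audit measures.
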