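# Desk-scale trade-off sweep: training size x note length, plus a
# key-phrase-count sweep for the synthetic-victim arm.
seed: 1
corpus:
  n_notes: 400
  n_codes: 20
  note_length_tokens: [40, 80]
  signature_injection_rate: 0.8
classifier:
  epochs: 15
  max_note_tokens: 96
attack:
  attack_models: [threshold, logistic, random_forest]
sweep:
  training_set_sizes: [240, 180, 120]
  max_note_tokens_values: [96, 72, 36]
  key_phrase_counts: [24, 12, 6]
  n_seed_replicates: 2
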