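# Two-wave synthetic scenario: the tight "red" group's opinion distribution
# contracts by a factor 2 in standard deviation between waves, while the wide
# "blue" group's opinions are unchanged. Under instantaneous lens updating the
# red group perceives strong lens-specific polarization (P2* > 0) although the
# objective opinion landscape barely moves.
seed: 21
item_names: [topic_x, topic_y]
shared_draws: true
waves:
  - label: w1
    groups:
      - {label: red,  n: 1000, mean: [0.30, 0.35], cov: [[0.0025, 0.0], [0.0, 0.0025]]}
      - {label: blue, n: 1000, mean: [0.72, 0.68], cov: [[0.0225, 0.0], [0.0, 0.0121]]}
  - label: w2
    groups:
      - {label: red,  n: 1000, mean: [0.30, 0.35], cov: [[0.000625, 0.0], [0.0, 0.000625]]}
      - {label: blue, n: 1000, mean: [0.72, 0.68], cov: [[0.0225, 0.0], [0.0, 0.0121]]}
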