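seed: 0
n_draws: 100
brackets:
  W_EE: [0.8, 1.6]
  W_EI: [0.4, 1.0]
  sigma_0E: [0.1, 0.4]
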