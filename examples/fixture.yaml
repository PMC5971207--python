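n_units: 100
n_trials: 50
mode: parametric
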