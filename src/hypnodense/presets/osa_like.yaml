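name: osa_like
transition_matrix:
  - [0.900, 0.090, 0.005, 0.005]
  - [0.040, 0.900, 0.040, 0.020]
  - [0.010, 0.060, 0.930, 0.000]
  - [0.025, 0.045, 0.000, 0.930]
concentration: 14.0
crossfade_epochs: 0
rem_leak: 0.05
manual_noise: 0.06
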