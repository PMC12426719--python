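name: rbd_like
transition_matrix:
  - [0.92, 0.070, 0.005, 0.005]
  - [0.03, 0.910, 0.040, 0.020]
  - [0.005, 0.065, 0.930, 0.000]
  - [0.02, 0.040, 0.000, 0.940]
concentration: 8.0
crossfade_epochs: 2
rem_leak: 0.35
manual_noise: 0.10
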