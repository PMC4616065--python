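params:
  decay_exc: 0.2
  decay_inh: 0.76
  upper_bound: 8.0
  lower_bound: 1.0
  R: 1.0
  W_exc: 0.23
  W_inh: 0.55
  I_exc_on: 4.0
  eta_exc: 0.25
  eta_inh: 0.205
  tau_gain: 0.15
  gamma: 5.0
  noise_amp: 0.0
network:
  locations: 1
  isolation: false
protocol:
  t_end: 16.0
  pulses:
  - target: s.exc_a
    onset: 5.0
    duration: 0.2
    amplitude: 4.0
  gi_pulses: []
windows:
  baseline:
  - 2.0
  - 5.0
  short_term:
  - 5.5
  - 8.5
  long_term:
  - 12.0
  - 15.0
sim:
  dt: 0.001
  seed: 0
  stride: 10
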