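# Three-state chain with the quencher nearest the intermediate state;
# the single-pulse fluorescence is biphasic (falls, then rises).
format_version: 1
units: {time: ms, voltage: mV, distance: A, charge: e0}
scheme:
  positions: [0.0, 5.0, 10.0]
  charges: [0.0, 1.6, 3.2]
  kT_mV: 25.4
  transitions:
    - {from: 0, to: 1, k0: 0.1, zdelta: 0.6}
    - {from: 1, to: 0, k0: 0.01, zdelta: -0.6}
    - {from: 1, to: 2, k0: 0.02, zdelta: 0.6}
    - {from: 2, to: 1, k0: 0.01, zdelta: -0.6}
geometry: {x_w: 4.0, lambda_half: 6.0, F0: 1.0}
protocol:
  holding_mV: -120.0
  sample_interval_ms: 0.05
  segments: [[10.0, -120.0], [50.0, 80.0]]
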