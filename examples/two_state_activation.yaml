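# Two-state voltage sensor, quencher at the active-state position.
# Units: time ms, voltage mV, distance Å, charge e0.
format_version: 1
units: {time: ms, voltage: mV, distance: A, charge: e0}
scheme:
  positions: [0.0, 10.0]
  charges: [0.0, 3.2]
  kT_mV: 25.4
  transitions:
    - {from: 0, to: 1, k0: 0.05, zdelta: 0.6}
    - {from: 1, to: 0, k0: 0.05, zdelta: -0.6}
geometry: {x_w: 10.0, lambda_half: 6.0, F0: 1000.0}
protocol:
  holding_mV: -120.0
  sample_interval_ms: 0.05
  segments: [[40.0, -120.0], [50.0, 80.0], [20.0, -120.0]]
noise: {gaussian_sd: 0.000154, drift_slope: 0.005, bleach_rate: 0.01, seed: 0}
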