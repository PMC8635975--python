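# vsdquench

Forward simulation and trace analysis for optical tracking of discrete
gating charges in voltage-sensing domains (VSDs) by
tryptophan-induced quenching of a charged bimane fluorophore (qBBr).

## Who this is for

Voltage-clamp fluorimetrists and modellers who want to (a) predict what a
qBBr-labelled gating charge should report as it moves past a quenching
tryptophan placed in or near its trajectory, and (b) exercise and validate
the standard cut-open-oocyte analysis chain (Bessel filtering, sweep
averaging, baseline subtraction, ΔF/F0, gating-charge integration,
exponential and Boltzmann fits, Cole–Moore prepulse analysis) on synthetic
recordings whose ground truth is known exactly.

## The model

The VSD is a continuous-time Markov chain over `n` conformational states.
State `i` carries a scalar trajectory coordinate `x_i` (Å) and a
cumulative gating charge `q_i` (e0); transition rates follow a
single-barrier exponential voltage dependence
`k_ij(V) = k0_ij · exp(zδ_ij · V / kT)`.

Tryptophan quenching of bimane is collisional, so the classical
Stern–Volmer concentration law, combined with `d ~ C^(-1/3)`, becomes a
distance law: the fraction of fluorescence surviving at quencher distance
`d` is

```
g(d) = 1 / (1 + (λ/d)³)
```

with `λ` the half-quench distance. A quencher at `x_w` then makes the
ensemble fluorescence

```
F(t) = F0 · Σ_i P_i(t) · g(|x_i − x_w|)
```

where `P_i(t)` solves the master equation under the voltage protocol.
Two consequences drive the analysis: for a two-state sensor the
normalized time course of `F(t)` equals `P_0(t)` regardless of where the
quencher sits (shape invariance), while with three or more states the
kinetics pick up extra exponential components and can even be biphasic
when the sensor dwells appreciably in an intermediate near the quencher.
A single molecule instead emits a telegraph-like step signal; a quencher
crossed only briefly mid-path darkens each molecule during its transit
yet leaves no resolvable dip in the unsynchronized ensemble.

The package provides the deterministic solver (matrix exponentials per
piecewise-constant protocol segment), an exact stochastic single-molecule
simulator with ensemble averaging, the full analysis pipeline, a
synthetic-recording generator with per-construct presets (background
dilution calibrated so each preset's noiseless ΔF/F0 at +80 mV matches
its published per-construct value), plain-text sweep/config formats, and
a CLI.

## Worked example

End-to-end recovery of a construct's fractional fluorescence change:
generate four noisy sweeps from the `R1C-qBBr` preset (ground-truth
ΔF/F0 = −0.154 % at +80 mV, i.e. a quench), Bessel-filter, average,
baseline-subtract and measure:

```
$ vsdquench recover --preset R1C-qBBr --seed 1 --out recover.json
INFO vsdquench: preset R1C-qBBr: target -0.1540 %, recovered -0.1516 % -> PASS
```

`recover.json` then contains

```json
{
  "command": "recover",
  "n_sweeps": 4,
  "pass": true,
  "preset": "R1C-qBBr",
  "recovered_dFF0_pct": -0.1515557818887629,
  "seed": 1,
  "target_dFF0_pct": -0.154,
  "tolerance_pct": 0.0172
}
```

The recovered value is the pipeline's estimate of ΔF/F0 in percent
(negative = quench); the tolerance is one standard error of the published
per-construct mean. The same machinery is available as a library:

```python
import vsdquench as vq

preset = vq.make_preset("R1C-qBBr:W454A;E247W")   # unquench, +0.930 %
protocol = vq.default_activation_protocol()        # -120 mV hold, +80 mV pulse
sweeps = vq.generate_sweep_set(preset, protocol, preset.default_noise(1))
avg = vq.average_sweeps(sweeps)
dff0 = vq.compute_dFF0(avg, baseline_window=(0, 40), response_window=(80, 90))
```

Other entry points: `simulate` (deterministic forward model from a YAML
config, see `examples/`), `singlemol` (stochastic ensemble), `generate`,
`analyze`, and `colemoore` (weighted-τ versus prepulse duration).

## Layout

- `src/vsdquench/state_model.py` — kinetic schemes, protocols, occupancy
  solver, steady states, gating currents, QV curves
- `src/vsdquench/quenching.py` — distance-quenching law and observables
- `src/vsdquench/stochastic.py` — single-molecule paths and ensembles
- `src/vsdquench/analysis.py` — filtering, ΔF/F0, charge integration,
  exponential/Boltzmann fits, QV/FV, Cole–Moore analysis
- `src/vsdquench/synth.py` — construct presets and recording generator
- `src/vsdquench/io.py`, `src/vsdquench/cli.py` — formats and CLI
- `docs/methods.md` — modelling assumptions, parameter choices, limits
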