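# Methods

## Model

The voltage-sensing domain is a continuous-time Markov chain on `n ≥ 2`
states connected at least as the linear chain `1 ↔ 2 ↔ … ↔ n`. Each state
carries a scalar coordinate `x_i` (Å) along the gating-charge trajectory
and a cumulative gating charge `q_i` (e0). Rates follow the
single-barrier exponential law `k_ij(V) = k0_ij · exp(zδ_ij · V / kT)`
with `kT/e0 = 25.4 mV` by default (≈ 22 °C). The underlying experiments
publish no rate model, so this standard VSD parameterization is a design
choice of the package; all preset rate constants are likewise tuned
artifact parameters targeting millisecond-scale activation, not measured
values.

Occupancies `P(t)` solve `dP/dt = P·Q(v(t))` under piecewise-constant
voltage protocols. The solution uses one matrix exponential per
(segment, step-length) pair, cached, so propagation is exact for the
commanded waveform; outputs are sampled on the protocol grid
(`sample_interval`, default 0.05 ms = 20 kHz, a deliberately reduced
stand-in for 50–100 kHz acquisition that keeps simulated sweeps compact).
Probability drift above 1e-12 triggers renormalization; drift above 1e-6
is an error. Ramps are not supported (none of the emulated protocols use
them).

Quenching follows the distance-rewritten Stern–Volmer law
`g(d) = 1/(1 + (λ/d)³)`; `g(0)` is defined as 0 (complete quenching at
contact) so a quencher coincident with a state position is legal. The
trajectory coordinate is one-dimensional: distances are `|x_i − x_w|`.
Whether `λ` is center-to-center or side-chain-adjusted is deliberately
left to the caller — it is a single parameter with no structural
interpretation here.

The deterministic observable is `F(t) = F0 · Σ_i P_i(t) g(|x_i − x_w|)`.
The stochastic simulator draws exponential waiting times from the current
state's total exit rate; at a protocol segment boundary the residual wait
is re-drawn under the new rates, which is exact (memorylessness), not an
approximation. Per-molecule seeds are `seed + molecule_index`; identical
seeds give bit-identical paths. Single-molecule output is intensity-level
only — no photon shot noise, blinking, or bleaching at that level.

## Tunable parameters

| parameter | default | units | rationale |
|---|---|---|---|
| `lambda_half` (λ) | 6 | Å | quenching is strong at van-der-Waals contact and falls below ~20 % by 10 Å, consistent with contact quenching requiring < 10 Å separations and the 10–15 Å Cα–Cα working range; no numeric λ is published |
| `kT` | 25.4 | mV | room-temperature recordings |
| `sample_interval` | 0.05 | ms | 20 kHz grid; scaled-down acquisition emulation |
| Bessel filter | 4-pole, causal, 1 kHz | — | mimics acquisition hardware; a zero-phase variant exists behind `bessel_lowpass_zero_phase` |
| `gaussian_sd` (default noise) | 0.1 × response amplitude | fraction of baseline F | per raw sweep, before 4-sweep averaging |
| `drift_slope` | 0.005 | fraction of F0 / s | slow lamp/stage drift |
| `bleach_rate` | 0.01 | 1/s | slow photobleaching; near-linear over ≤ 1 s sweeps, hence removed by the linear baseline |

## Construct presets

Each preset couples a kinetic scheme, a quencher geometry, and a
background dilution to a published per-construct ΔF/F0 at +80 mV
(percent, signed; negative = quench). Observed magnitudes are sub-percent
because most collected fluorescence is not coupled to the channel; the
generator models this with an explicit `background_fraction` `b`, solved
in closed form so that

```
ΔF/F0 = 100 · (1−b)·(g_ss(+80) − g_ss(hold)) / (b + (1−b)·g_ss(hold))
```

equals the target exactly (`g_ss(V)` is the steady-state mean quench
factor). This self-consistency is enforced at construction time, so a
preset cannot drift away from its target.

"No effect" constructs carry a small, fast, voltage-independent additive
transient (first-order relaxation, τ = 0.5 ms, amplitude set by the
published row) instead of a quenching signal; its physical origin is
unresolved in the source experiments and is emulated phenomenologically
only. The quencher for these presets sits equidistant from both end
states so the kinetic scheme contributes no voltage-dependent signal.

A `deep-closed-state` preset (4-state chain deep ↔ C1 ↔ C2 ↔ active)
models the Cole–Moore regime: the deep state is entered slowly
(~0.9 s time constant at −160 mV) and exited slowly (~12 ms at +80 mV),
so longer hyperpolarizing prepulses load it further and the test-pulse
fluorescence acquires a larger slow component — the weighted τ increases
strictly across 80 ms / 1 s / 5 s prepulses. Its +0.5 % target is an
artifact choice (the corresponding published construct is a "no effect"
row at depolarized potentials; its Cole–Moore fluorescence is reported
only qualitatively).

## Analysis pipeline choices

- Order fixed as filter → baseline subtraction (unstated in the emulated
  workflow); 0-based sample indexing; windows are half-open `[start, end)`
  in ms; t = 0 at sweep start; the pulse onset comes from the protocol,
  never from the data.
- ΔF/F0: least-squares line over the baseline window, extrapolated and
  subtracted; `F0` is the fitted baseline value at pulse onset (the
  published definition fixes the subtraction window but not the
  evaluation point). Response window defaults to the last 20 % of the
  test pulse. The optional confidence interval assumes i.i.d. Gaussian
  noise (baseline-prediction variance plus response-mean standard
  error) — filtering correlates samples and would make it anti-
  conservative, so the coverage guarantee applies to unfiltered input.
- "Weighted" double-exponential τ is the amplitude-weighted mean
  `Σ|A_k|τ_k / Σ|A_k|` — the conventional reading; the emulated workflow
  does not define its weighting.
- Charge integration: a single line fit over user-chosen quiescent
  windows (defaults: final stretches of the pre- and post-pulse holding
  periods) is subtracted before trapezoidal integration.
- QV/FV normalization is per recording (per oocyte in the emulated
  experiments): QV min/max to [0, 1], FV by max |value|; multi-recording
  curves aggregate after normalization, reported mean ± SEM.
- Exponential fits use bounded nonlinear least squares with up to 8
  log-perturbed-τ restarts from a fixed internal seed; non-convergence
  raises with diagnostics. τ are sorted ascending; ties in the
  double-exponential fit are therefore reported deterministically.

## What the generator does and does not emulate

Emulated: small fractional signals on a large uncoupled background,
additive Gaussian noise per raw sweep, consecutive-sweep averaging,
linear drift, slow photobleaching, gating currents from the same
occupancy trajectory (scaled to µA for ~1e9 channels), deterministic
seeding. Not emulated: capacitive transients and leak (recordings are
treated as leak-subtracted), absolute photodetector units,
oocyte-to-oocyte variability beyond per-recording scale factors, photon
shot noise, fluorophore photophysics beyond the static quench factor,
and conducting-pore currents (the emulated constructs are
non-conducting). Passing tests therefore demonstrate correctness of the
model and pipeline under these idealized conditions, not robustness to
every artifact of real recordings.

## Numerical and testing notes

- Problem sizes are chosen to keep the full suite in tens of seconds:
  10,000-molecule ensembles on coarse (0.1 ms) grids, 200-seed
  Monte-Carlo loops on ~700-sample sweeps, 5 s prepulses at 10 kHz.
- The master-equation solver is cross-checked against a fine-step
  explicit-Euler integration; that oracle is first-order, so the
  comparison uses a mild-rate scheme where the oracle's own error is well
  below the 1e-6 comparison band.
- The mid-path-quencher ensemble test uses a transit fast enough
  (exit ≈ 1.3e4/ms at +80 mV) that the expected ensemble dip lies below
  the 10,000-molecule noise floor, matching the regime in which the
  single-molecule event is invisible in bulk.
- Degenerate inputs fail loudly: disconnected schemes name their
  components, zero-span QV normalization, non-positive F0 after baseline
  correction, out-of-range windows, overflowing rates at extreme V·zδ.

## Known limitations

Rate constants and the deep-state topology are plausible but invented;
quantitative kinetics of the presets should not be read as measurements.
The 1-D trajectory coordinate cannot express rotamer- or
orientation-dependent quenching. The CI on ΔF/F0 is approximate under
filtering (see above). HDF5 output mirrors the CSV schema but stores no
extra metadata beyond it.
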