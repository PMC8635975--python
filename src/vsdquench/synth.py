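"""Synthetic cut-open-oocyte recordings with known ground truth.

The generator emulates simultaneous fluorescence / gating-current
acquisition: a small voltage-dependent fluorescence signal riding on a
large uncoupled background, slow photobleaching, linear baseline drift,
additive Gaussian noise, and consecutive-sweep averaging. Construct
presets are keyed to published per-construct fractional fluorescence
changes at +80 mV (percent, signed); each preset's background dilution is
calibrated in closed form so the noiseless steady-state dF/F0 equals its
target exactly.

Kinetic rate constants of the presets are tuned artifact parameters
targeting millisecond-scale activation; they are not measured values.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .analysis import SweepRecording
from .quenching import QuencherGeometry, quench_factor
from .state_model import (
    KineticScheme,
    VoltageProtocol,
    gating_current,
    solve_occupancies,
    steady_state,
)

__all__ = [
    "NoiseModel",
    "ConstructPreset",
    "available_presets",
    "make_preset",
    "generate_sweep",
    "generate_sweep_set",
    "generate_protocol_family",
    "generate_cole_moore_set",
    "default_activation_protocol",
]

E0_UA_MS = 1.602176634e-10  # 1 e0/ms expressed in µA


@dataclass(frozen=True)
class NoiseModel:
    """Acquisition noise: Gaussian SD, baseline drift, photobleach (per s)."""

    gaussian_sd: float = 0.0  # fraction of baseline fluorescence, per raw sweep
    drift_slope: float = 0.0  # fraction of baseline fluorescence per s
    bleach_rate: float = 0.0  # 1/s
    seed: int = 0

    def __post_init__(self):
        if self.gaussian_sd < 0:
            raise ValueError("gaussian_sd must be >= 0")
        if self.bleach_rate < 0:
            raise ValueError("bleach_rate must be >= 0")


_EFFECT_CLASSES = ("quench", "unquench", "no effect")


@dataclass(frozen=True)
class ConstructPreset:
    """Ground-truth parameter bundle for one labelled construct.

    ``background_fraction`` is the fraction of total fluorescence not
    coupled to the channel; it dilutes the full quenching contrast down to
    the sub-percent dF/F0 observed on oocytes. For "no effect" constructs
    the target amplitude is carried by a fast voltage-independent residual
    transient (time constant ``residual_tau`` ms) rather than by
    quenching.
    """

    label: str
    scheme: KineticScheme
    geometry: QuencherGeometry
    background_fraction: float
    target_dFF0_at_80mV: float  # percent, signed
    effect_class: str
    sem: float = 0.0  # printed SEM, for tolerance bookkeeping
    residual_tau: float = 0.5  # ms
    holding_voltage: float = -120.0

    def __post_init__(self):
        if self.effect_class not in _EFFECT_CLASSES:
            raise ValueError(f"effect_class must be one of {_EFFECT_CLASSES}")
        if not 0 <= self.background_fraction < 1:
            raise ValueError("background_fraction must lie in [0, 1)")
        pred = self.predicted_dFF0(80.0)
        if abs(pred - self.target_dFF0_at_80mV) > 1e-3:
            raise ValueError(
                f"preset {self.label!r} is inconsistent: predicted "
                f"{pred:.6f}% != target {self.target_dFF0_at_80mV:.6f}%"
            )
        if self.effect_class == "quench" and not self.target_dFF0_at_80mV < 0:
            raise ValueError("quench presets need a negative target")
        if self.effect_class == "unquench" and not self.target_dFF0_at_80mV > 0:
            raise ValueError("unquench presets need a positive target")

    @property
    def positions(self) -> Tuple[float, ...]:
        return self.scheme.positions

    def _mean_quench(self, voltage: float) -> float:
        g = quench_factor(
            np.abs(np.asarray(self.positions) - self.geometry.x_w),
            self.geometry.lambda_half,
        )
        return float(steady_state(self.scheme, voltage) @ g)

    def predicted_dFF0(self, voltage: float) -> float:
        """Noiseless steady-state dF/F0 (%) at a test voltage, from the
        quenching observable diluted by the background (plus the residual
        amplitude for "no effect" presets)."""
        b = self.background_fraction
        g_hold = self._mean_quench(self.holding_voltage)
        g_test = self._mean_quench(voltage)
        base = b + (1 - b) * g_hold
        value = 100.0 * (1 - b) * (g_test - g_hold) / base
        if self.effect_class == "no effect":
            value += self.target_dFF0_at_80mV
        return value

    def default_noise(self, seed: int = 0) -> NoiseModel:
        """Default acquisition noise: per-sweep Gaussian SD of 10% of the
        pulse-response amplitude, mild drift and photobleach."""
        sd = 0.1 * abs(self.target_dFF0_at_80mV) / 100.0
        return NoiseModel(gaussian_sd=sd, drift_slope=0.005, bleach_rate=0.01, seed=seed)


def _background_for_target(
    scheme: KineticScheme,
    geometry: QuencherGeometry,
    holding: float,
    target_pct: float,
    test_voltage: float = 80.0,
) -> float:
    """Solve the dilution fraction b so the steady-state dF/F0 equals the target."""
    g = quench_factor(
        np.abs(np.asarray(scheme.positions) - geometry.x_w), geometry.lambda_half
    )
    g_hold = float(steady_state(scheme, holding) @ g)
    g_test = float(steady_state(scheme, test_voltage) @ g)
    dg = g_test - g_hold
    r = target_pct / 100.0
    if dg == 0:
        raise ValueError("zero quenching contrast; cannot calibrate background")
    b = (dg - r * g_hold) / (r * (1 - g_hold) + dg)
    if not 0 <= b < 1:
        raise ValueError(f"calibrated background fraction {b} outside [0, 1)")
    return b


# ---------------------------------------------------------------------------
# preset registry: (target dF/F0 % at +80 mV, printed SEM, effect class)

TABLE1: Dict[str, Tuple[float, float, str]] = {
    "R1C-qBBr": (-0.154, 0.0172, "quench"),
    "R1C-qBBr:W454A": (0.206, 0.037, "no effect"),
    "R1C-qBBr:W454A;F244W": (0.191, 0.026, "unquench"),
    "R1C-qBBr:W454A;E247W": (0.930, 0.205, "unquench"),
    "R1C-qBBr:W454A;F290W": (0.0946, 0.0323, "no effect"),
    "R1C-qBBr:W454A;L294W": (0.127, 0.086, "no effect"),
    "R1C-qBBr:W454A;I320W": (0.247, 0.095, "unquench"),
    "R1C-qBBr:W454A;T326W": (0.448, 0.167, "unquench"),
    "R1C-qBBr:W454A;Y415W": (-0.147, 0.015, "quench"),
    "R2C-qBBr": (0.168, 0.0241, "no effect"),
    "R2C-qBBr:I241W": (0.261, 0.132, "unquench"),
    "R2C-qBBr:F244W": (0.454, 0.171, "unquench"),
    "R2C-qBBr:I287W": (0.493, 0.156, "unquench"),
    "R2C-qBBr:L294W": (0.183, 0.036, "unquench"),
    "R2C-qBBr:T326W": (-0.094, 0.017, "quench"),
    "R2C-qBBr:Y415W": (-0.851, 0.123, "quench"),
    "R2C-qBBr:F416W": (-0.0448, 0.098, "quench"),
}

DEEP_STATE_LABEL = "deep-closed-state"
_HOLDING = -120.0
_F_TOTAL = 1000.0  # arbitrary photodiode units


def _two_state_scheme() -> KineticScheme:
    # resting at 0 Å, active at 10 Å; ~3 ms activation at +80 mV, z = 1.2
    return KineticScheme.linear_chain(
        positions=(0.0, 10.0),
        charges=(0.0, 3.2),
        forward=[(0.05, 0.6)],
        backward=[(0.05, -0.6)],
    )


def _deep_state_scheme() -> KineticScheme:
    """Four-state chain deep <-> C1 <-> C2 <-> active.

    The deep closed state is populated slowly (~0.9 s time constant) at
    -160 mV and exits slowly (~12 ms) on depolarization, producing a
    Cole-Moore-type slowing after long hyperpolarizing prepulses.
    """
    return KineticScheme.linear_chain(
        positions=(-5.0, 0.0, 3.0, 10.0),
        charges=(-1.0, 0.0, 1.5, 3.2),
        forward=[(0.0127, 0.584), (0.05, 0.8), (0.02, 1.0)],
        backward=[(3.5e-5, -0.5), (0.05, -0.8), (0.02, -1.0)],
    )


def three_state_biphasic() -> Tuple[KineticScheme, QuencherGeometry]:
    """Three-state fixture whose single-pulse fluorescence is biphasic.

    The quencher sits nearest the intermediate state (x_w = 4 Å between
    states at 0, 5 and 10 Å) and the intermediate dwell time at +80 mV is
    comparable to the transit time, so fluorescence first falls as the
    intermediate populates, then rises as the sensor reaches the end state.
    """
    scheme = KineticScheme.linear_chain(
        positions=(0.0, 5.0, 10.0),
        charges=(0.0, 1.6, 3.2),
        forward=[(0.1, 0.6), (0.02, 0.6)],
        backward=[(0.01, -0.6), (0.01, -0.6)],
    )
    return scheme, QuencherGeometry(x_w=4.0, lambda_half=6.0, F0=1.0)


def three_state_brief_dwell() -> Tuple[KineticScheme, QuencherGeometry]:
    """Brief-dwell variant of :func:`three_state_biphasic`: the intermediate
    empties ~200x faster than it fills, so the single-pulse fluorescence is
    monotonic yet carries two exponential components."""
    scheme = KineticScheme.linear_chain(
        positions=(0.0, 5.0, 10.0),
        charges=(0.0, 1.6, 3.2),
        forward=[(0.1, 0.6), (4.0, 0.6)],
        backward=[(0.01, -0.6), (0.01, -0.6)],
    )
    return scheme, QuencherGeometry(x_w=4.0, lambda_half=6.0, F0=1.0)


def available_presets() -> List[str]:
    return list(TABLE1) + [DEEP_STATE_LABEL]


def make_preset(label: str) -> ConstructPreset:
    """Build the named construct preset (self-consistent by construction)."""
    if label == DEEP_STATE_LABEL:
        scheme = _deep_state_scheme()
        geometry = QuencherGeometry(x_w=-5.0, lambda_half=6.0, F0=_F_TOTAL)
        target = 0.5  # artifact choice: unquench on depolarization
        b = _background_for_target(scheme, geometry, _HOLDING, target)
        return ConstructPreset(
            label=label,
            scheme=scheme,
            geometry=geometry,
            background_fraction=b,
            target_dFF0_at_80mV=target,
            effect_class="unquench",
            sem=0.0,
        )
    if label not in TABLE1:
        raise ValueError(
            f"unknown preset {label!r}; available: {', '.join(available_presets())}"
        )
    target, sem, effect = TABLE1[label]
    scheme = _two_state_scheme()
    if effect == "quench":
        geometry = QuencherGeometry(x_w=10.0, lambda_half=6.0, F0=_F_TOTAL)
    elif effect == "unquench":
        geometry = QuencherGeometry(x_w=0.0, lambda_half=6.0, F0=_F_TOTAL)
    else:
        # voltage-neutral placement: equidistant from both end states
        geometry = QuencherGeometry(x_w=5.0, lambda_half=6.0, F0=_F_TOTAL)
    if effect == "no effect":
        b = 0.995
    else:
        b = _background_for_target(scheme, geometry, _HOLDING, target)
    return ConstructPreset(
        label=label,
        scheme=scheme,
        geometry=geometry,
        background_fraction=b,
        target_dFF0_at_80mV=target,
        effect_class=effect,
        sem=sem,
    )


# ---------------------------------------------------------------------------
# protocols


def default_activation_protocol(
    voltage: float = 80.0,
    holding: float = _HOLDING,
    baseline_ms: float = 40.0,
    pulse_ms: float = 50.0,
    tail_ms: float = 20.0,
    sample_interval: float = 0.05,
) -> VoltageProtocol:
    return VoltageProtocol(
        segments=((baseline_ms, holding), (pulse_ms, voltage), (tail_ms, holding)),
        holding_voltage=holding,
        sample_interval=sample_interval,
    )


def generate_protocol_family(
    kind: str,
    voltages: Sequence[float],
    holding: float,
    pulse_ms: float,
    baseline_ms: float = 40.0,
    tail_ms: float = 20.0,
    conditioning_voltage: float = 80.0,
    conditioning_ms: Optional[float] = None,
    sample_interval: float = 0.05,
) -> List[VoltageProtocol]:
    """Activation (hold -> V -> hold) or deactivation (hold -> conditioning
    depolarization -> V -> hold) protocol families over a list of test
    voltages."""
    if kind not in ("activation", "deactivation"):
        raise ValueError("kind must be 'activation' or 'deactivation'")
    if len(voltages) == 0:
        raise ValueError("need at least one test voltage")
    cond = pulse_ms if conditioning_ms is None else conditioning_ms
    out = []
    for v in voltages:
        if kind == "activation":
            segs = ((baseline_ms, holding), (pulse_ms, v), (tail_ms, holding))
        else:
            segs = (
                (baseline_ms, holding),
                (cond, conditioning_voltage),
                (pulse_ms, v),
                (tail_ms, holding),
            )
        out.append(
            VoltageProtocol(
                segments=segs, holding_voltage=holding, sample_interval=sample_interval
            )
        )
    return out


# ---------------------------------------------------------------------------
# sweep generation


def _residual_signal(
    protocol: VoltageProtocol, times: np.ndarray, tau_ms: float
) -> np.ndarray:
    """First-order relaxation toward 1 whenever the command leaves holding.

    Phenomenological model of the small fast voltage-independent residual
    transient seen in tryptophan-free constructs; same amplitude and
    kinetics at every pulse voltage.
    """
    target = (protocol.voltage_series(times) != protocol.holding_voltage).astype(float)
    dt = protocol.sample_interval
    alpha = 1.0 - np.exp(-dt / tau_ms)
    s = np.empty_like(target)
    level = 0.0
    for k, tgt in enumerate(target):
        level += (tgt - level) * alpha
        s[k] = level
    return s


def generate_sweep(
    preset: ConstructPreset,
    protocol: VoltageProtocol,
    noise: NoiseModel,
    n_channels: float = 1e9,
) -> SweepRecording:
    """One synthetic raw sweep: fluorescence + gating current.

    Fluorescence = total baseline * [b + (1-b) * sum_i P_i(t) g_i],
    multiplied by the photobleach decay, plus linear drift and i.i.d.
    Gaussian noise (both scaled to the baseline fluorescence). The gating
    current (µA) derives from the same occupancy trajectory.
    Deterministic given ``noise.seed``.
    """
    scheme = preset.scheme
    p0 = steady_state(scheme, protocol.holding_voltage)
    occ = solve_occupancies(scheme, protocol, p0)
    times = occ.times
    g = quench_factor(
        np.abs(np.asarray(preset.positions) - preset.geometry.x_w),
        preset.geometry.lambda_half,
    )
    gbar = occ.probabilities @ g
    b = preset.background_fraction
    f = preset.geometry.F0 * (b + (1 - b) * gbar)
    f_base = float(f[0])
    if preset.effect_class == "no effect":
        amp = (preset.target_dFF0_at_80mV / 100.0) * f_base
        f = f + amp * _residual_signal(protocol, times, preset.residual_tau)
    t_s = times / 1000.0
    f = f * np.exp(-noise.bleach_rate * t_s)
    f = f + noise.drift_slope * t_s * f_base
    rng = np.random.default_rng(noise.seed)
    if noise.gaussian_sd > 0:
        f = f + rng.normal(0.0, noise.gaussian_sd * f_base, size=f.size)
    _, ig = gating_current(occ, scheme, n_channels=n_channels)
    ig_ua = ig * E0_UA_MS
    if noise.gaussian_sd > 0:
        peak = np.abs(ig_ua).max()
        if peak > 0:
            ig_ua = ig_ua + rng.normal(0.0, noise.gaussian_sd * peak, size=ig_ua.size)
    return SweepRecording(
        protocol=protocol,
        sample_rate=1.0 / protocol.sample_interval,
        fluorescence=f,
        gating_current=ig_ua,
        n_averaged=1,
        construct_label=preset.label,
    )


def generate_sweep_set(
    preset: ConstructPreset,
    protocol: VoltageProtocol,
    noise: NoiseModel,
    n_sweeps: int = 4,
    n_channels: float = 1e9,
) -> List[SweepRecording]:
    """Consecutive raw sweeps; sweep seeds are ``noise.seed + index``."""
    return [
        generate_sweep(preset, protocol, replace(noise, seed=noise.seed + i), n_channels)
        for i in range(n_sweeps)
    ]


def generate_cole_moore_set(
    preset: ConstructPreset,
    prepulse_voltage: float,
    durations: Sequence[float],
    test_pulse: Tuple[float, float] = (80.0, 100.0),
    holding: float = _HOLDING,
    baseline_ms: float = 40.0,
    tail_ms: float = 20.0,
    sample_interval: float = 0.1,
    noise: Optional[NoiseModel] = None,
    n_sweeps: int = 4,
) -> Dict[Tuple[float, float], List[SweepRecording]]:
    """Prepulse-duration families sharing an identical test pulse.

    Returns ``{(prepulse_voltage, duration_ms): [sweeps]}``; group g uses
    seeds ``noise.seed + 1000*g + sweep_index`` so groups are independent
    but fixed.
    """
    if not durations:
        raise ValueError("need at least one prepulse duration")
    test_v, test_ms = test_pulse
    noise = noise if noise is not None else NoiseModel()
    out: Dict[Tuple[float, float], List[SweepRecording]] = {}
    for gidx, dur in enumerate(durations):
        pre_seg = ((float(dur), prepulse_voltage),) if dur > 0 else ()
        proto = VoltageProtocol(
            segments=(
                (baseline_ms, holding),
                *pre_seg,
                (test_ms, test_v),
                (tail_ms, holding),
            ),
            holding_voltage=holding,
            sample_interval=sample_interval,
        )
        group_noise = replace(noise, seed=noise.seed + 1000 * gidx)
        out[(prepulse_voltage, float(dur))] = generate_sweep_set(
            preset, proto, group_noise, n_sweeps=n_sweeps
        )
    return out
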