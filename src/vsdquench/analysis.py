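"""Voltage-clamp-fluorimetry trace analysis.

Implements the acquisition-style processing chain used on cut-open-oocyte
recordings: causal Bessel low-pass filtering, consecutive-sweep averaging,
linear baseline subtraction with fractional fluorescence change (dF/F0),
gating-charge integration, single / weighted-double exponential fitting,
per-recording-normalized QV and FV curves with Boltzmann summaries, and
Cole–Moore prepulse analysis.

Conventions: time origin t = 0 at sweep start; windows are half-open
[start, end) in ms; dF/F0 is in percent, signed, negative = quench.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import signal, stats
from scipy.optimize import curve_fit

from .state_model import DEFAULT_KT_MV, VoltageProtocol

__all__ = [
    "SweepRecording",
    "ExponentialFit",
    "VoltageCurve",
    "ColeMooreResult",
    "bessel_lowpass",
    "average_sweeps",
    "compute_dFF0",
    "integrate_charge",
    "fit_exponential",
    "exponential_order_test",
    "build_voltage_curve",
    "boltzmann_fit",
    "cole_moore_tau",
    "pulse_onset",
]


@dataclass(frozen=True)
class SweepRecording:
    """One (possibly averaged) fluorescence + gating-current sweep."""

    protocol: VoltageProtocol
    sample_rate: float  # kHz
    fluorescence: np.ndarray  # arbitrary units
    gating_current: Optional[np.ndarray] = None  # µA
    n_averaged: int = 1
    construct_label: str = ""

    def __post_init__(self):
        f = np.asarray(self.fluorescence, float)
        object.__setattr__(self, "fluorescence", f)
        if self.sample_rate < 1.0:
            raise ValueError("sample_rate must be >= 1 kHz")
        dt = 1.0 / self.sample_rate
        if abs(dt - self.protocol.sample_interval) > 1e-9 * max(dt, 1.0):
            raise ValueError("sample_rate inconsistent with protocol sample_interval")
        n = self.protocol.n_samples
        if f.size != n:
            raise ValueError(
                f"fluorescence length {f.size} != protocol samples {n}"
            )
        if self.gating_current is not None:
            g = np.asarray(self.gating_current, float)
            object.__setattr__(self, "gating_current", g)
            if g.size != n:
                raise ValueError("gating_current length != protocol samples")
        if self.n_averaged < 1:
            raise ValueError("n_averaged must be >= 1")

    @property
    def times(self) -> np.ndarray:
        return self.protocol.times()


@dataclass(frozen=True)
class ExponentialFit:
    """offset + sum_k A_k exp(-t/tau_k), taus sorted ascending (ms)."""

    order: int
    amplitudes: Tuple[float, ...]
    taus: Tuple[float, ...]
    offset: float
    residual_sum_squares: float

    def __post_init__(self):
        if self.order not in (1, 2):
            raise ValueError("order must be 1 or 2")
        if len(self.amplitudes) != self.order or len(self.taus) != self.order:
            raise ValueError("amplitudes/taus length must equal order")
        if any(t <= 0 for t in self.taus):
            raise ValueError("all taus must be > 0")

    @property
    def weighted_tau(self) -> float:
        """Amplitude-weighted mean time constant, sum|A_k| tau_k / sum|A_k|."""
        a = np.abs(self.amplitudes)
        if a.sum() == 0:
            return float(np.mean(self.taus))
        return float(np.dot(a, self.taus) / a.sum())

    def evaluate(self, t) -> np.ndarray:
        tt = np.asarray(t, float)
        out = np.full(tt.shape, self.offset)
        for a, tau in zip(self.amplitudes, self.taus):
            out = out + a * np.exp(-tt / tau)
        return out


@dataclass(frozen=True)
class VoltageCurve:
    """QV or FV relation; optionally per-recording normalized and aggregated."""

    kind: str  # "QV" or "FV"
    points: Tuple[Tuple[float, float], ...]
    normalized: bool = False
    per_recording_id: str = ""
    sem: Optional[Tuple[float, ...]] = None

    def __post_init__(self):
        if self.kind not in ("QV", "FV"):
            raise ValueError("kind must be 'QV' or 'FV'")
        pts = tuple((float(v), float(y)) for v, y in self.points)
        object.__setattr__(self, "points", pts)
        volts = [v for v, _ in pts]
        if len(set(volts)) != len(volts):
            raise ValueError("voltages must be unique")
        if self.normalized:
            vals = np.array([y for _, y in pts])
            if self.kind == "QV" and (vals.min() < -1e-9 or vals.max() > 1 + 1e-9):
                raise ValueError("normalized QV values must lie in [0, 1]")
            if self.kind == "FV" and np.any(np.abs(vals) > 1 + 1e-9):
                raise ValueError("normalized FV values must lie in [-1, 1]")

    @property
    def voltages(self) -> np.ndarray:
        return np.array([v for v, _ in self.points])

    @property
    def values(self) -> np.ndarray:
        return np.array([y for _, y in self.points])


@dataclass(frozen=True)
class ColeMooreResult:
    """Weighted tau per (prepulse_voltage mV, prepulse_duration ms) condition."""

    entries: Tuple[Tuple[float, float, float], ...]  # (V_pre, dur_ms, tau_w)


# ---------------------------------------------------------------------------
# filtering and averaging


def bessel_lowpass(samples, sample_rate: float, cutoff: float) -> np.ndarray:
    """Causal 4-pole low-pass Bessel filter (rates in kHz), length-preserving.

    Mimics the analog acquisition filter; initial conditions are set for a
    step of the first sample's value, so a constant input passes unchanged.
    Set ``zero_phase=True`` is not offered here; see
    :func:`bessel_lowpass_zero_phase` for the offline variant.
    """
    if not 0 < cutoff < sample_rate / 2:
        raise ValueError("cutoff must lie in (0, Nyquist)")
    x = np.asarray(samples, float)
    b, a = signal.bessel(4, cutoff / (sample_rate / 2), btype="low", norm="mag")
    zi = signal.lfilter_zi(b, a) * x[0]
    y, _ = signal.lfilter(b, a, x, zi=zi)
    return y


def bessel_lowpass_zero_phase(samples, sample_rate: float, cutoff: float) -> np.ndarray:
    """Zero-phase (forward-backward) variant of :func:`bessel_lowpass`."""
    if not 0 < cutoff < sample_rate / 2:
        raise ValueError("cutoff must lie in (0, Nyquist)")
    x = np.asarray(samples, float)
    b, a = signal.bessel(4, cutoff / (sample_rate / 2), btype="low", norm="mag")
    return signal.filtfilt(b, a, x)


def _protocols_equal(p1: VoltageProtocol, p2: VoltageProtocol) -> bool:
    return (
        p1.segments == p2.segments
        and p1.holding_voltage == p2.holding_voltage
        and p1.sample_interval == p2.sample_interval
    )


def average_sweeps(sweeps: Sequence[SweepRecording]) -> SweepRecording:
    """Pointwise mean of consecutively acquired sweeps.

    All inputs must share the protocol and sample rate; ``n_averaged``
    of the result is the sum of the inputs'.
    """
    if not sweeps:
        raise ValueError("no sweeps to average")
    first = sweeps[0]
    for s in sweeps[1:]:
        if s.sample_rate != first.sample_rate or not _protocols_equal(
            s.protocol, first.protocol
        ):
            raise ValueError("sweeps must share protocol and sample rate")
    f = np.mean([s.fluorescence for s in sweeps], axis=0)
    if all(s.gating_current is not None for s in sweeps):
        g = np.mean([s.gating_current for s in sweeps], axis=0)
    else:
        g = None
    return SweepRecording(
        protocol=first.protocol,
        sample_rate=first.sample_rate,
        fluorescence=f,
        gating_current=g,
        n_averaged=sum(s.n_averaged for s in sweeps),
        construct_label=first.construct_label,
    )


# ---------------------------------------------------------------------------
# baseline subtraction and dF/F0


def pulse_onset(protocol: VoltageProtocol) -> float:
    """Time (ms) of the first commanded voltage change, from the protocol."""
    edges = protocol.boundaries
    volts = [v for _, v in protocol.segments]
    for i in range(len(volts) - 1):
        if volts[i + 1] != volts[i]:
            return float(edges[i])
    return float(edges[0])


def _window_mask(times: np.ndarray, window: Tuple[float, float]) -> np.ndarray:
    start, end = window
    if end <= start:
        raise ValueError(f"empty window {window}")
    mask = (times >= start) & (times < end)
    if times.size and (start < 0 or end > times[-1] + (times[1] - times[0])):
        raise ValueError(f"window {window} lies outside the trace")
    return mask


def _fit_baseline(times, samples, window):
    mask = _window_mask(times, window)
    if mask.sum() < 2:
        raise ValueError("baseline window must contain at least 2 samples")
    coef = np.polyfit(times[mask], samples[mask], 1)
    return coef, mask


def compute_dFF0(
    sweep: SweepRecording,
    baseline_window: Tuple[float, float],
    response_window: Tuple[float, float],
    with_ci: bool = False,
):
    """Fractional fluorescence change dF/F0 in percent (negative = quench).

    A least-squares line fit over ``baseline_window`` (which must precede
    the pulse onset) is extrapolated and subtracted across the sweep; F0
    is the fitted baseline value at the pulse onset, and dF/F0 is
    100 * mean(corrected fluorescence over ``response_window``) / F0.

    With ``with_ci=True`` also returns a 95% confidence interval derived
    from the baseline residual variance (i.i.d.-noise prediction interval
    for the extrapolated line plus the response-mean standard error).
    """
    t = sweep.times
    f = sweep.fluorescence
    onset = pulse_onset(sweep.protocol)
    if baseline_window[1] > onset + 1e-9:
        raise ValueError(
            f"baseline window {baseline_window} must precede pulse onset {onset} ms"
        )
    coef, bmask = _fit_baseline(t, f, baseline_window)
    baseline = np.polyval(coef, t)
    corrected = f - baseline
    F0 = float(np.polyval(coef, onset))
    if F0 <= 0:
        raise ValueError(f"F0 = {F0} <= 0 after baseline fit")
    rmask = _window_mask(t, response_window)
    if not rmask.any():
        raise ValueError("response window contains no samples")
    dff0 = 100.0 * float(np.mean(corrected[rmask])) / F0
    if not with_ci:
        return dff0
    # variance of the response mean about the extrapolated baseline
    tb = t[bmask]
    resid = f[bmask] - np.polyval(coef, tb)
    nb = tb.size
    s2 = float(resid @ resid) / max(nb - 2, 1)
    sxx = float(np.sum((tb - tb.mean()) ** 2))
    t_resp_mean = float(t[rmask].mean())
    var_pred = s2 * (1.0 / nb + (t_resp_mean - tb.mean()) ** 2 / sxx)
    var_mean = s2 / rmask.sum() + var_pred
    half = 1.96 * 100.0 * np.sqrt(var_mean) / F0
    return dff0, (dff0 - half, dff0 + half)


def integrate_charge(
    gating_trace,
    sample_rate: float,
    baseline_windows: Sequence[Tuple[float, float]],
    integration_window: Optional[Tuple[float, float]] = None,
) -> float:
    """Time-integral of the gating current after linear baseline removal.

    ``baseline_windows`` are user-chosen quiescent periods (ms) where the
    current has returned to zero; a single line is fit over their union
    and subtracted. The integral (trapezoidal) runs over
    ``integration_window`` (default: the whole trace). Units: input µA and
    kHz give nC * 1e-3 (µA·ms).
    """
    x = np.asarray(gating_trace, float)
    t = np.arange(x.size) / sample_rate
    if not baseline_windows:
        raise ValueError("need at least one baseline window")
    mask = np.zeros(x.size, bool)
    for w in baseline_windows:
        mask |= _window_mask(t, w)
    if mask.sum() < 2:
        raise ValueError("baseline windows contain fewer than 2 samples")
    coef = np.polyfit(t[mask], x[mask], 1)
    corrected = x - np.polyval(coef, t)
    if integration_window is None:
        imask = np.ones(x.size, bool)
    else:
        imask = _window_mask(t, integration_window)
        if not imask.any():
            raise ValueError("integration window contains no samples")
    return float(np.trapezoid(corrected[imask], t[imask]))


# ---------------------------------------------------------------------------
# exponential fitting


def _exp_model(order):
    if order == 1:

        def f(t, a1, tau1, c):
            return c + a1 * np.exp(-t / tau1)

    else:

        def f(t, a1, tau1, a2, tau2, c):
            return c + a1 * np.exp(-t / tau1) + a2 * np.exp(-t / tau2)

    return f


def fit_exponential(samples, times, order: int = 1) -> ExponentialFit:
    """Nonlinear least-squares fit of offset + sum_k A_k exp(-t/tau_k).

    Time is measured from ``times[0]``. Taus are bounded positive and
    returned sorted ascending; several perturbed restarts are attempted
    before giving up.
    """
    if order not in (1, 2):
        raise ValueError("order must be 1 or 2")
    y = np.asarray(samples, float)
    t = np.asarray(times, float) - np.asarray(times, float)[0]
    if y.size < 10:
        raise ValueError("need at least 10 samples in the fit window")
    span = t[-1] if t[-1] > 0 else 1.0
    amp0 = y[0] - y[-1]
    off0 = y[-1]
    model = _exp_model(order)
    if order == 1:
        p0s = [[amp0, span / 5, off0]]
        lb = [-np.inf, 1e-9, -np.inf]
        ub = [np.inf, np.inf, np.inf]
    else:
        p0s = [[amp0 / 2, span / 10, amp0 / 2, span / 2, off0]]
        lb = [-np.inf, 1e-9, -np.inf, 1e-9, -np.inf]
        ub = [np.inf] * 5
    rng = np.random.default_rng(0)
    last_err: Exception | None = None
    for attempt in range(8):
        if attempt > 0:
            base = p0s[0]
            p0 = list(base)
            # perturb the tau entries log-uniformly
            tau_idx = [1] if order == 1 else [1, 3]
            for k in tau_idx:
                p0[k] = base[k] * float(np.exp(rng.uniform(-2.0, 2.0)))
            p0s.append(p0)
        try:
            popt, _ = curve_fit(
                model, t, y, p0=p0s[attempt], bounds=(lb, ub), maxfev=20000
            )
        except (RuntimeError, ValueError) as err:  # pragma: no cover - rare
            last_err = err
            continue
        resid = y - model(t, *popt)
        rss = float(resid @ resid)
        if order == 1:
            a, taus, off = (popt[0],), (popt[1],), popt[2]
        else:
            pairs = sorted([(popt[1], popt[0]), (popt[3], popt[2])])
            taus = (pairs[0][0], pairs[1][0])
            a = (pairs[0][1], pairs[1][1])
            off = popt[4]
        return ExponentialFit(order, a, taus, float(off), rss)
    raise RuntimeError(
        f"exponential fit (order {order}) failed after 8 restarts: {last_err}"
    )


def exponential_order_test(samples, times) -> Tuple[ExponentialFit, ExponentialFit, float]:
    """Nested F-test comparing 1- vs 2-exponential fits.

    Returns (fit1, fit2, p_value); small p favours the 2-exponential model.
    """
    fit1 = fit_exponential(samples, times, order=1)
    fit2 = fit_exponential(samples, times, order=2)
    n = np.asarray(samples).size
    df1, df2 = 2, n - 5
    rss1, rss2 = fit1.residual_sum_squares, fit2.residual_sum_squares
    if rss2 <= 0:
        return fit1, fit2, 0.0
    F = ((rss1 - rss2) / df1) / (rss2 / df2)
    p = float(stats.f.sf(max(F, 0.0), df1, df2))
    return fit1, fit2, p


# ---------------------------------------------------------------------------
# voltage curves


def build_voltage_curve(
    values: Sequence[Tuple[float, float, str]],
    kind: str,
    normalize: bool = True,
) -> VoltageCurve:
    """Aggregate per-voltage values into a QV or FV curve.

    Normalization is performed for each recording separately: QV is mapped
    to [0, 1] by its own min/max, FV is divided by its own max |value|.
    Multi-recording curves then report mean +/- standard error per voltage.
    """
    by_rec: Dict[str, List[Tuple[float, float]]] = {}
    for v, y, rid in values:
        by_rec.setdefault(rid, []).append((float(v), float(y)))
    if not by_rec:
        raise ValueError("no values provided")
    normed: Dict[str, Dict[float, float]] = {}
    for rid, pts in by_rec.items():
        if len({v for v, _ in pts}) < 2:
            raise ValueError(f"recording {rid!r} has fewer than 2 voltages")
        arr = np.array([y for _, y in pts])
        if normalize:
            if kind == "QV":
                span = arr.max() - arr.min()
                if span <= 0:
                    raise ValueError(f"recording {rid!r} has zero QV span")
                arr = (arr - arr.min()) / span
            else:
                m = np.abs(arr).max()
                if m <= 0:
                    raise ValueError(f"recording {rid!r} has zero FV amplitude")
                arr = arr / m
        normed[rid] = {v: a for (v, _), a in zip(pts, arr)}
    if len(normed) == 1:
        rid, d = next(iter(normed.items()))
        pts = tuple(sorted(d.items()))
        return VoltageCurve(kind, pts, normalized=normalize, per_recording_id=rid)
    volts = sorted({v for d in normed.values() for v in d})
    means, sems = [], []
    for v in volts:
        vals = np.array([d[v] for d in normed.values() if v in d])
        means.append(vals.mean())
        sems.append(vals.std(ddof=1) / np.sqrt(vals.size) if vals.size > 1 else 0.0)
    pts = tuple(zip(volts, means))
    return VoltageCurve(
        kind, pts, normalized=normalize, per_recording_id="mean", sem=tuple(sems)
    )


def boltzmann_fit(curve: VoltageCurve, kT: float = DEFAULT_KT_MV) -> Tuple[float, float]:
    """Two-state Boltzmann fit Q(V) = 1 / (1 + exp(-z (V - V1/2) / kT)).

    Returns (V_half in mV, z in e0). Requires a QV curve with >= 4 points.
    """
    if curve.kind != "QV":
        raise ValueError("boltzmann_fit expects a QV curve")
    v = curve.voltages
    q = curve.values
    if v.size < 4:
        raise ValueError("need at least 4 points for a Boltzmann fit")

    def model(vv, vhalf, z):
        return 1.0 / (1.0 + np.exp(-z * (vv - vhalf) / kT))

    vh0 = float(v[np.argmin(np.abs(q - 0.5))])
    try:
        popt, _ = curve_fit(model, v, q, p0=[vh0, 1.0], maxfev=20000)
    except RuntimeError as err:
        raise RuntimeError(f"Boltzmann fit did not converge: {err}") from err
    return float(popt[0]), float(popt[1])


# ---------------------------------------------------------------------------
# Cole-Moore analysis


def cole_moore_tau(
    groups: Dict[Tuple[float, float], Sequence[SweepRecording]],
    fit_window: Optional[Tuple[float, float]] = None,
    baseline_window: Optional[Tuple[float, float]] = None,
) -> ColeMooreResult:
    """Weighted double-exponential tau of the test-pulse fluorescence per
    prepulse condition.

    ``groups`` maps (prepulse_voltage mV, prepulse_duration ms) to sweeps
    recorded with protocols of the form hold -> prepulse -> test -> hold,
    identical except for the prepulse. Each group is averaged,
    baseline-corrected (linear fit over ``baseline_window``, default the
    pre-prepulse holding segment), and the test-pulse phase (default: the
    segment following the prepulse, relative ``fit_window`` in ms from
    test onset) is fit with a weighted double exponential.
    """
    if not groups:
        raise ValueError("no prepulse groups provided")
    # validate: segments after the prepulse identical across groups
    test_shapes = set()
    for (v_pre, dur), sweeps in groups.items():
        proto = sweeps[0].protocol
        if len(proto.segments) < 3:
            raise ValueError("protocols must be hold -> prepulse -> test [...]")
        test_shapes.add(proto.segments[2:])
    if len(test_shapes) != 1:
        raise ValueError("test pulses differ across prepulse groups")

    entries = []
    for (v_pre, dur) in sorted(groups, key=lambda k: (k[0], k[1])):
        avg = average_sweeps(list(groups[(v_pre, dur)]))
        t = avg.times
        proto = avg.protocol
        edges = proto.boundaries
        test_start, test_end = float(edges[1]), float(edges[2])
        bw = baseline_window if baseline_window is not None else (0.0, float(edges[0]))
        coef, _ = _fit_baseline(t, avg.fluorescence, bw)
        corrected = avg.fluorescence - np.polyval(coef, t)
        if fit_window is None:
            w0, w1 = test_start, test_end
        else:
            w0, w1 = test_start + fit_window[0], test_start + fit_window[1]
        mask = _window_mask(t, (w0, w1))
        fit = fit_exponential(corrected[mask], t[mask], order=2)
        entries.append((float(v_pre), float(dur), fit.weighted_tau))
    return ColeMooreResult(tuple(entries))
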