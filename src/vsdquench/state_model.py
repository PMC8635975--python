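"""Continuous-time Markov model of a voltage-sensing domain.

The voltage sensor is described as an ``n``-state chain. Each state ``i``
carries a scalar coordinate ``x_i`` (Å) along the gating-charge trajectory
and a cumulative gating charge ``q_i`` (elementary charges, e0). Transition
rates follow a single-barrier exponential voltage dependence

    k_ij(V) = k0_ij * exp(zdelta_ij * V / kT)

with ``kT`` expressed in mV (kT/e0, ~25.4 mV at room temperature). Units
throughout: time in ms, voltage in mV, distance in Å, charge in e0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np
from scipy.linalg import expm, null_space

__all__ = [
    "VoltageProtocol",
    "KineticScheme",
    "OccupancyTrajectory",
    "rate_matrix",
    "solve_occupancies",
    "steady_state",
    "gating_current",
    "charge_voltage_curve",
]

DEFAULT_KT_MV = 25.4

# probability-drift thresholds for the propagated master equation
_RENORM_TOL = 1e-12
_DRIFT_ERROR_TOL = 1e-6


@dataclass(frozen=True)
class VoltageProtocol:
    """Piecewise-constant voltage-clamp command.

    ``segments`` is an ordered list of ``(duration_ms, voltage_mV)``;
    voltage is constant on left-closed, right-open intervals. Before t=0
    the membrane sits at ``holding_voltage``.
    """

    segments: Tuple[Tuple[float, float], ...]
    holding_voltage: float
    sample_interval: float  # ms

    def __post_init__(self):
        segs = tuple((float(d), float(v)) for d, v in self.segments)
        object.__setattr__(self, "segments", segs)
        if not segs:
            raise ValueError("protocol must contain at least one segment")
        for d, v in segs:
            if not d > 0:
                raise ValueError(f"segment duration must be > 0, got {d}")
            if not np.isfinite(v):
                raise ValueError("segment voltage must be finite")
        if not self.sample_interval > 0:
            raise ValueError("sample_interval must be > 0")

    @property
    def total_duration(self) -> float:
        return float(sum(d for d, _ in self.segments))

    @property
    def boundaries(self) -> np.ndarray:
        """Cumulative segment end times, length n_segments."""
        return np.cumsum([d for d, _ in self.segments])

    @property
    def n_samples(self) -> int:
        return int(round(self.total_duration / self.sample_interval))

    def times(self) -> np.ndarray:
        """Sample grid t_k = k*dt, k = 0 .. n_samples-1 (left-closed)."""
        return np.arange(self.n_samples) * self.sample_interval

    def voltage_at(self, t: float) -> float:
        if t < 0:
            return self.holding_voltage
        edge = 0.0
        for d, v in self.segments:
            edge += d
            if t < edge:
                return v
        return self.segments[-1][1]

    def voltage_series(self, times: Sequence[float] | None = None) -> np.ndarray:
        tt = self.times() if times is None else np.asarray(times, float)
        return np.array([self.voltage_at(t) for t in tt])

    def segment_index(self, t: float) -> int:
        edge = 0.0
        for i, (d, _) in enumerate(self.segments):
            edge += d
            if t < edge:
                return i
        return len(self.segments) - 1


@dataclass(frozen=True)
class KineticScheme:
    """n-state kinetic scheme with per-state trajectory positions and charges.

    ``transitions`` maps directed pairs ``(i, j)`` (0-based) to
    ``(base_rate k0 [1/ms], voltage_sensitivity zdelta [e0])``. Connectivity
    must contain at least the linear chain 0<->1<->...<->n-1.
    """

    positions: Tuple[float, ...]  # Å
    charges: Tuple[float, ...]  # e0, cumulative; need not be monotone
    transitions: Dict[Tuple[int, int], Tuple[float, float]]
    kT: float = DEFAULT_KT_MV  # mV (kT / e0)

    def __post_init__(self):
        pos = tuple(float(x) for x in self.positions)
        chg = tuple(float(q) for q in self.charges)
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "charges", chg)
        n = len(pos)
        if n < 2:
            raise ValueError("scheme needs at least 2 states")
        if len(chg) != n:
            raise ValueError("positions and charges must have equal length")
        if not all(np.isfinite(pos)) or not all(np.isfinite(chg)):
            raise ValueError("positions and charges must be finite")
        trans = {
            (int(i), int(j)): (float(k0), float(zd))
            for (i, j), (k0, zd) in self.transitions.items()
        }
        object.__setattr__(self, "transitions", trans)
        for (i, j), (k0, _) in trans.items():
            if i == j or not (0 <= i < n and 0 <= j < n):
                raise ValueError(f"invalid transition ({i}, {j})")
            if k0 < 0:
                raise ValueError(f"base rate for ({i}, {j}) must be >= 0")
        for i in range(n - 1):
            if (i, i + 1) not in trans or (i + 1, i) not in trans:
                raise ValueError(
                    "transitions must contain the linear chain "
                    f"{i}<->{i + 1} (missing)"
                )
        if not self.kT > 0:
            raise ValueError("kT must be > 0 mV")

    @property
    def n_states(self) -> int:
        return len(self.positions)

    @classmethod
    def linear_chain(
        cls,
        positions: Sequence[float],
        charges: Sequence[float],
        forward: Sequence[Tuple[float, float]],
        backward: Sequence[Tuple[float, float]],
        kT: float = DEFAULT_KT_MV,
    ) -> "KineticScheme":
        """Build a 1<->2<->...<->n chain from per-step (k0, zdelta) pairs."""
        n = len(positions)
        if len(forward) != n - 1 or len(backward) != n - 1:
            raise ValueError("need n-1 forward and backward rate pairs")
        trans: Dict[Tuple[int, int], Tuple[float, float]] = {}
        for i in range(n - 1):
            trans[(i, i + 1)] = tuple(forward[i])
            trans[(i + 1, i)] = tuple(backward[i])
        return cls(tuple(positions), tuple(charges), trans, kT)

    def connected_components(self) -> List[List[int]]:
        """Undirected components of the positive-rate transition graph."""
        adj: Dict[int, set] = {i: set() for i in range(self.n_states)}
        for (i, j), (k0, _) in self.transitions.items():
            if k0 > 0:
                adj[i].add(j)
                adj[j].add(i)
        seen: set = set()
        comps = []
        for start in range(self.n_states):
            if start in seen:
                continue
            stack, comp = [start], []
            while stack:
                u = stack.pop()
                if u in seen:
                    continue
                seen.add(u)
                comp.append(u)
                stack.extend(adj[u] - seen)
            comps.append(sorted(comp))
        return comps


@dataclass(frozen=True)
class OccupancyTrajectory:
    """State probabilities P_i(t) on a time grid (times in ms)."""

    times: np.ndarray
    probabilities: np.ndarray  # shape (n_times, n_states)

    def __post_init__(self):
        t = np.asarray(self.times, float)
        p = np.asarray(self.probabilities, float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "probabilities", p)
        if t.ndim != 1 or p.ndim != 2 or p.shape[0] != t.size:
            raise ValueError("times and probabilities shapes do not match")
        if t.size and (t[0] != 0 or np.any(np.diff(t) <= 0)):
            raise ValueError("times must be strictly increasing from 0")
        sums = p.sum(axis=1)
        if np.any(np.abs(sums - 1) > 1e-9):
            raise ValueError("probability vectors must sum to 1 within 1e-9")
        if np.any(p < -1e-12) or np.any(p > 1 + 1e-12):
            raise ValueError("probabilities must lie in [0, 1]")

    @property
    def n_states(self) -> int:
        return self.probabilities.shape[1]

    def mean_charge(self, scheme: KineticScheme) -> np.ndarray:
        return self.probabilities @ np.asarray(scheme.charges)


def rate_matrix(scheme: KineticScheme, voltage: float) -> np.ndarray:
    """Generator matrix Q(V) in 1/ms; rows sum to zero.

    Off-diagonal (i, j) is k_ij(V) = k0_ij * exp(zdelta_ij * V / kT); the
    diagonal is minus the row sum. Overflow at extreme V*zdelta raises.
    """
    if not np.isfinite(voltage):
        raise ValueError("voltage must be finite")
    n = scheme.n_states
    Q = np.zeros((n, n))
    with np.errstate(over="ignore"):
        for (i, j), (k0, zd) in scheme.transitions.items():
            Q[i, j] = k0 * np.exp(zd * voltage / scheme.kT)
    if not np.all(np.isfinite(Q)):
        raise ValueError(
            "non-finite transition rate (voltage-sensitivity overflow); "
            "check zdelta * V magnitudes"
        )
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def solve_occupancies(
    scheme: KineticScheme,
    protocol: VoltageProtocol,
    initial: Sequence[float],
) -> OccupancyTrajectory:
    """Propagate dP/dt = P Q(v(t)) segment-by-segment via matrix exponentials.

    The solution is exact for piecewise-constant voltage; output is sampled
    on the protocol grid. ``initial`` must sum to 1 within 1e-6.
    """
    p = np.asarray(initial, float)
    if p.shape != (scheme.n_states,):
        raise ValueError("initial occupancy length must match n_states")
    if abs(p.sum() - 1) > 1e-6:
        raise ValueError("initial occupancies must sum to 1 within 1e-6")
    p = p / p.sum()

    times = protocol.times()
    bounds = protocol.boundaries
    seg_Q = [rate_matrix(scheme, v) for _, v in protocol.segments]

    prop_cache: Dict[Tuple[int, float], np.ndarray] = {}

    def propagator(seg: int, dt: float) -> np.ndarray:
        key = (seg, round(dt, 12))
        if key not in prop_cache:
            prop_cache[key] = expm(seg_Q[seg] * dt)
        return prop_cache[key]

    out = np.empty((times.size, scheme.n_states))
    out[0] = p
    for k in range(1, times.size):
        t0, t1 = times[k - 1], times[k]
        t = t0
        while t < t1 - 1e-12:
            seg = int(np.searchsorted(bounds, t, side="right"))
            seg = min(seg, len(bounds) - 1)
            t_next = min(t1, bounds[seg])
            p = p @ propagator(seg, t_next - t)
            t = t_next
        drift = abs(p.sum() - 1)
        if drift > _DRIFT_ERROR_TOL:
            raise RuntimeError(f"probability drift {drift:.2e} exceeds 1e-6")
        if drift > _RENORM_TOL:
            p = p / p.sum()
        p = np.clip(p, 0.0, 1.0)
        p = p / p.sum()
        out[k] = p
    return OccupancyTrajectory(times, out)


def steady_state(scheme: KineticScheme, voltage: float) -> np.ndarray:
    """Stationary distribution: normalized null vector of Q(V)."""
    comps = scheme.connected_components()
    if len(comps) > 1:
        raise ValueError(f"scheme is disconnected; components: {comps}")
    Q = rate_matrix(scheme, voltage)
    ns = null_space(Q.T)
    if ns.shape[1] != 1:
        raise ValueError(
            f"generator has {ns.shape[1]} zero eigenvalues; "
            "stationary distribution is not unique"
        )
    p = ns[:, 0]
    p = p / p.sum()
    if np.any(p < -1e-10):
        raise RuntimeError("negative entries in stationary distribution")
    p = np.clip(p, 0.0, None)
    return p / p.sum()


def gating_current(
    occupancy: OccupancyTrajectory,
    scheme: KineticScheme,
    n_channels: float = 1.0,
) -> Tuple[np.ndarray, np.ndarray]:
    """Gating current I_g(t) = n_channels * d<q>/dt by central differences.

    Returns ``(times_ms, current)`` with current in e0/ms * n_channels.
    """
    if occupancy.n_states != scheme.n_states:
        raise ValueError("occupancy and scheme state counts differ")
    qbar = occupancy.mean_charge(scheme)
    ig = n_channels * np.gradient(qbar, occupancy.times)
    return occupancy.times, ig


def charge_voltage_curve(
    scheme: KineticScheme, voltages: Sequence[float]
) -> Tuple[np.ndarray, np.ndarray]:
    """Steady-state QV curve, min-max normalized to [0, 1]."""
    volts = np.asarray(voltages, float)
    if volts.size < 2:
        raise ValueError("need at least 2 voltages")
    charges = np.asarray(scheme.charges)
    q = np.array([charges @ steady_state(scheme, v) for v in volts])
    span = q.max() - q.min()
    if span <= 0:
        raise ValueError("charge span is zero; QV cannot be normalized")
    return volts, (q - q.min()) / span
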