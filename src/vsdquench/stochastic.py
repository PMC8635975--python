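"""Single-molecule stochastic trajectories and their ensemble average.

A single voltage sensor hops between discrete states; under a constant
voltage its waiting time in state i is exponential with the total exit
rate. At a protocol segment boundary the rates change; by memorylessness
the residual waiting time is simply re-drawn under the new rates, so the
simulation is exact for piecewise-constant voltage (no discretization).

The per-molecule fluorescence is a telegraph-like step signal F0*g(d(t));
averaging n molecules converges to the deterministic ensemble observable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np

from .quenching import QuencherGeometry, quench_factor
from .state_model import KineticScheme, VoltageProtocol, rate_matrix

__all__ = ["StatePath", "EnsembleResult", "simulate_path", "path_fluorescence", "ensemble_average"]


@dataclass(frozen=True)
class StatePath:
    """One molecule's state history: (entry_time_ms, state) events."""

    events: Tuple[Tuple[float, int], ...]
    total_duration: float

    def __post_init__(self):
        ev = tuple((float(t), int(s)) for t, s in self.events)
        object.__setattr__(self, "events", ev)
        if not ev or ev[0][0] != 0.0:
            raise ValueError("first event must occur at t = 0")
        t_prev, s_prev = ev[0]
        for t, s in ev[1:]:
            if t <= t_prev:
                raise ValueError("entry times must be strictly increasing")
            if s == s_prev:
                raise ValueError("consecutive states must differ")
            t_prev, s_prev = t, s

    def state_at(self, times) -> np.ndarray:
        """Right-continuous state lookup on an array of times."""
        tt = np.asarray(times, float)
        entry = np.array([t for t, _ in self.events])
        states = np.array([s for _, s in self.events])
        idx = np.searchsorted(entry, tt, side="right") - 1
        return states[idx]


@dataclass(frozen=True)
class EnsembleResult:
    times: np.ndarray
    mean_F: np.ndarray
    standard_error: np.ndarray
    n_molecules: int

    def __post_init__(self):
        if self.n_molecules < 1:
            raise ValueError("n_molecules must be >= 1")
        if np.any(np.asarray(self.standard_error) < 0):
            raise ValueError("standard_error must be >= 0")


def simulate_path(
    scheme: KineticScheme,
    protocol: VoltageProtocol,
    seed: int,
    initial_state: int | None = None,
) -> StatePath:
    """Exact stochastic path under piecewise-constant rates.

    When ``initial_state`` is None the start state is drawn from the
    holding-voltage stationary distribution, so ensembles begin
    equilibrated at the holding potential. Identical seeds give
    identical paths.
    """
    rng = np.random.default_rng(seed)
    if initial_state is None:
        from .state_model import steady_state

        p_hold = steady_state(scheme, protocol.holding_voltage)
        state = int(rng.choice(scheme.n_states, p=p_hold))
    else:
        state = int(initial_state)
        if not 0 <= state < scheme.n_states:
            raise ValueError("initial_state out of range")
    total = protocol.total_duration
    bounds = protocol.boundaries
    seg_Q = [rate_matrix(scheme, v) for _, v in protocol.segments]

    events: List[Tuple[float, int]] = [(0.0, state)]
    t = 0.0
    seg = 0
    while t < total:
        Q = seg_Q[seg]
        exit_rate = -Q[state, state]
        seg_end = bounds[seg]
        if exit_rate <= 0:
            wait = np.inf
        else:
            wait = rng.exponential(1.0 / exit_rate)
        if t + wait >= seg_end:
            # no jump before the boundary; re-draw under the next segment's rates
            t = seg_end
            seg += 1
            if seg >= len(seg_Q):
                break
            continue
        t = t + wait
        rates = Q[state].copy()
        rates[state] = 0.0
        state = int(rng.choice(scheme.n_states, p=rates / rates.sum()))
        events.append((t, state))
    return StatePath(tuple(events), total)


def path_fluorescence(
    path: StatePath,
    positions: Sequence[float],
    geometry: QuencherGeometry,
    times,
) -> np.ndarray:
    """Piecewise-constant single-molecule fluorescence F0*g(|x_state(t) - x_w|)."""
    tt = np.asarray(times, float)
    if np.any(tt < 0) or np.any(tt > path.total_duration):
        raise ValueError("times must lie within [0, path duration]")
    pos = np.asarray(positions, float)
    g = quench_factor(np.abs(pos - geometry.x_w), geometry.lambda_half)
    return geometry.F0 * g[path.state_at(tt)]


def ensemble_average(
    scheme: KineticScheme,
    protocol: VoltageProtocol,
    positions: Sequence[float],
    geometry: QuencherGeometry,
    n_molecules: int,
    seed: int,
    initial_state: int | None = None,
) -> EnsembleResult:
    """Mean +/- standard error of n independent single-molecule traces.

    Per-molecule seeds are ``seed + index`` (documented, reproducible).
    With n = 1 the standard error is reported as 0.
    """
    if n_molecules < 1:
        raise ValueError("n_molecules must be >= 1")
    times = protocol.times()
    total = np.zeros(times.size)
    total_sq = np.zeros(times.size)
    for m in range(n_molecules):
        path = simulate_path(scheme, protocol, seed + m, initial_state=initial_state)
        f = path_fluorescence(path, positions, geometry, times)
        total += f
        total_sq += f * f
    mean = total / n_molecules
    if n_molecules == 1:
        sem = np.zeros_like(mean)
    else:
        var = (total_sq - n_molecules * mean**2) / (n_molecules - 1)
        sem = np.sqrt(np.clip(var, 0.0, None) / n_molecules)
    return EnsembleResult(times, mean, sem, n_molecules)
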