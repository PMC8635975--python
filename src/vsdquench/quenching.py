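"""Distance form of Stern–Volmer tryptophan quenching and its observables.

Collisional quenching of a bimane fluorophore by tryptophan follows the
Stern–Volmer concentration law; with d ~ C^(-1/3) it becomes a distance
law: the fraction of fluorescence surviving at quencher distance d is

    g(d) = 1 / (1 + (lambda / d)^3)

where ``lambda`` is the half-quench distance (g(lambda) = 1/2). A moving
fluorophore with state occupancies P_i(t) and per-state positions x_i emits

    F(t) = F0 * sum_i P_i(t) * g(|x_i - x_w|).

For two states this is affine in P_0(t): the normalized time course equals
P_0(t) and is independent of the quencher placement.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .state_model import OccupancyTrajectory

__all__ = [
    "QuencherGeometry",
    "quench_factor",
    "distance_from_concentration",
    "two_state_fluorescence",
    "ensemble_fluorescence",
]


@dataclass(frozen=True)
class QuencherGeometry:
    """Quencher position and quenching scale.

    x_w : quencher coordinate on the trajectory axis (Å)
    lambda_half : distance at which half the fluorescence is quenched (Å)
    F0 : unquenched fluorescence intensity (arbitrary units)
    """

    x_w: float
    lambda_half: float = 6.0
    F0: float = 1.0

    def __post_init__(self):
        if not np.isfinite(self.x_w):
            raise ValueError("x_w must be finite")
        if not self.lambda_half > 0:
            raise ValueError(f"lambda_half must be > 0, got {self.lambda_half}")
        if not self.F0 > 0:
            raise ValueError(f"F0 must be > 0, got {self.F0}")


def quench_factor(distance, lambda_half: float):
    """Surviving fluorescence fraction g(d) = 1 / (1 + (lambda/d)^3).

    Defined as 0 at d = 0 (complete quenching at contact); strictly
    increasing in d, approaching 1 at large distance. Accepts scalars
    or arrays of distances (Å).
    """
    if not lambda_half > 0:
        raise ValueError("lambda_half must be > 0")
    d = np.asarray(distance, float)
    if np.any(d < 0):
        raise ValueError("distance must be >= 0")
    # d^3 / (d^3 + lambda^3) avoids the 0/0 at contact
    d3 = d**3
    out = d3 / (d3 + lambda_half**3)
    return out if out.ndim else float(out)


def distance_from_concentration(concentration, scale: float):
    """Map an effective quencher concentration to a distance, d = scale * C^(-1/3).

    ``scale`` (Å · units^(1/3)) is the explicit proportionality constant of
    the d ~ 1/C^(1/3) relation.
    """
    c = np.asarray(concentration, float)
    if np.any(c <= 0):
        raise ValueError("concentration must be > 0")
    if not scale > 0:
        raise ValueError("scale must be > 0")
    out = scale * c ** (-1.0 / 3.0)
    return out if out.ndim else float(out)


def two_state_fluorescence(
    P0_of_t,
    x0: float,
    xf: float,
    x_w: float,
    lambda_half: float,
):
    """Normalized two-state fluorescence time course F(t)/F0.

    F/F0 = P0(t) * [g(|x0 - x_w|) - g(|xf - x_w|)] + g(|xf - x_w|).
    Affine in P0, so the normalized kinetics are those of P0(t) whatever
    the quencher placement.
    """
    p0 = np.asarray(P0_of_t, float)
    if np.any(p0 < -1e-12) or np.any(p0 > 1 + 1e-12):
        raise ValueError("P0 values must lie in [0, 1]")
    g0 = quench_factor(abs(x0 - x_w), lambda_half)
    gf = quench_factor(abs(xf - x_w), lambda_half)
    return p0 * (g0 - gf) + gf


def ensemble_fluorescence(
    occupancy: OccupancyTrajectory,
    positions: Sequence[float],
    geometry: QuencherGeometry,
) -> np.ndarray:
    """Deterministic ensemble fluorescence F(t) = F0 * sum_i P_i(t) g(|x_i - x_w|)."""
    pos = np.asarray(positions, float)
    if pos.size != occupancy.n_states:
        raise ValueError(
            f"positions length {pos.size} != occupancy states {occupancy.n_states}"
        )
    g = quench_factor(np.abs(pos - geometry.x_w), geometry.lambda_half)
    return geometry.F0 * (occupancy.probabilities @ g)
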