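import numpy as np
import pytest

from vsdquench import KineticScheme, QuencherGeometry, VoltageProtocol


@pytest.fixture
def two_state():
    """Symmetric-rate-law two-state sensor, ms-scale kinetics, z = 1.2."""
    return KineticScheme.linear_chain(
        positions=(0.0, 10.0),
        charges=(0.0, 3.2),
        forward=[(0.05, 0.6)],
        backward=[(0.05, -0.6)],
    )


@pytest.fixture
def three_state():
    return KineticScheme.linear_chain(
        positions=(0.0, 5.0, 10.0),
        charges=(0.0, 1.6, 3.2),
        forward=[(0.2, 0.5), (0.05, 0.7)],
        backward=[(0.03, -0.4), (0.02, -0.6)],
    )


@pytest.fixture
def step_protocol():
    """hold -> +80 mV step -> hold, 20 kHz."""
    return VoltageProtocol(
        segments=((10.0, -120.0), (30.0, 80.0), (20.0, -120.0)),
        holding_voltage=-120.0,
        sample_interval=0.05,
    )


@pytest.fixture
def geometry_active():
    """Quencher at the active-state position (quench on activation)."""
    return QuencherGeometry(x_w=10.0, lambda_half=6.0, F0=1.0)


def random_chain(rng: np.random.Generator, n_states: int) -> KineticScheme:
    """Random connected chain scheme for property tests."""
    forward = [(10 ** rng.uniform(-2, 0.5), rng.uniform(0, 1.5)) for _ in range(n_states - 1)]
    backward = [(10 ** rng.uniform(-2, 0.5), -rng.uniform(0, 1.5)) for _ in range(n_states - 1)]
    positions = np.sort(rng.uniform(0, 20, n_states))
    charges = np.cumsum(rng.uniform(0, 2, n_states))
    return KineticScheme.linear_chain(positions, charges, forward, backward)
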