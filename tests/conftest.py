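import numpy as np
import pandas as pd
import pytest

import oida
from oida.signals_io import (
    CRANK_COL,
    THIGH_COLS,
    TIME_COL,
    TORQUE_COLS,
)


def make_frames(
    t_ms,
    crank=None,
    torque_left=0.0,
    torque_right=0.0,
    thigh_left=40.0,
    thigh_right=40.0,
    **extra,
):
    """Build a frame stream from arrays/scalars, filling unused channels."""
    t = np.asarray(t_ms, dtype=float)
    n = len(t)

    def col(v):
        return np.full(n, v, dtype=float) if np.ndim(v) == 0 else np.asarray(v, float)

    data = {
        TIME_COL: t,
        CRANK_COL: np.mod(col(0.0 if crank is None else crank), 360.0),
        TORQUE_COLS[0]: col(torque_left),
        TORQUE_COLS[1]: col(torque_right),
        THIGH_COLS[0]: col(thigh_left),
        THIGH_COLS[1]: col(thigh_right),
    }
    for k, v in extra.items():
        data[k] = col(v)
    return pd.DataFrame(data)


def make_crank_cycle(angles, torques, side="left", duration_ms=12000.0):
    """One crank cycle from (angle, torque) samples; time spaced uniformly."""
    angles = np.asarray(angles, dtype=float)
    t = np.linspace(0.0, duration_ms, len(angles))
    frames = make_frames(
        t,
        crank=angles,
        torque_left=torques if side == "left" else 0.0,
        torque_right=torques if side == "right" else 0.0,
    )
    return oida.Cycle(frames=frames, start_t=-1.0, end_t=duration_ms + 1.0, kind="crank")


def circ_err(a, b, span=360.0):
    """Circular distance between two positions."""
    return min((a - b) % span, (b - a) % span)


@pytest.fixture(scope="session")
def default_session():
    """One deterministic noiseless-ish default simulated session."""
    return oida.simulate_session(oida.SimulationConfig(seed=7))


@pytest.fixture
def zero_delays():
    return oida.DelayModel(0.0, 0.0, 0.0)
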