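"""Synthetic pedalling sessions with known ground truth.

The generator is a phenomenological torque model of the fitting protocol: an
examiner turns the cranks by hand at a slow target cadence (default 5 RPM,
small per-cycle jitter) while the instrumented crank records per-side torque.
Passive torque is gravity-dominated and modelled as the first two harmonics
of the crank angle (legs act half a revolution apart).  During the active
segment the stimulated muscle adds a raised-cosine torque bump that is
strictly positive exactly on the configured ground-truth interval, plus an
optional negative lobe on the rest of the revolution that mimics the
eccentric, resisting action of the muscle outside its useful range (the
resisting torque typically exceeds the contributing one).  Thigh angles are
a fixed sinusoidal function of the crank angle, so IMU-based cycling-phase
analysis sees a geometry consistent with the crank.  Per-sensor transmission
delays are *applied* to the emitted streams (the power-meter channels lag by
200 ms, the IMU channels by 40 ms), so the alignment step of the pipeline
has real work to undo, and white Gaussian measurement noise can be added to
the torque channels.  Everything is deterministic under the configured seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .signals_io import (
    CRANK_COL,
    STIM_COL,
    THIGH_COLS,
    TIME_COL,
    TORQUE_COLS,
    WHEEL_COL,
)
from .types import CHANNEL_SIDES, DelayModel, StimulationInterval

#: Thigh-geometry model: thigh = offset + amplitude * cos(crank - phase),
#: with the left leg half a revolution ahead of the right.
THIGH_PHASE_DEG = {"right": 270.0, "left": 90.0}


@dataclass
class SimulationConfig:
    """Ground truth and protocol parameters of one synthetic session.

    Defaults mirror the fitting protocol: 5 RPM target cadence with mild
    per-cycle jitter, enough generated cycles to supply 3 accepted passive
    and 3 accepted-and-usable active cycles (the first active cycle is
    discarded downstream), power-meter/IMU latencies of 200/40 ms, and a
    left-quadriceps ground-truth interval that wraps through 0 deg.
    """

    channel: str = "LQ"
    true_interval: StimulationInterval = field(
        default_factory=lambda: StimulationInterval(259.0, 68.0, span=360.0)
    )
    peak_torque_nm: float = 5.0
    negative_lobe_fraction: float = 1.2  # eccentric lobe depth / peak; 0 = off
    passive_amp1_nm: float = 5.0
    passive_amp2_nm: float = 1.0
    passive_offset_nm: float = 0.0
    passive_phase_deg: float = 0.0
    target_cadence_rpm: float = 5.0
    cadence_jitter: float = 0.1  # fractional, uniform per cycle
    noise_sd_nm: float = 0.0
    activation_lag_ms: float = 0.0
    onset_transient_nm: float = 2.0  # extra torque spike in the 1st active cycle
    n_passive: int = 4
    n_active: int = 5
    sample_hz: float = 100.0
    delays: DelayModel = field(default_factory=DelayModel)
    thigh_offset_deg: float = 40.0
    thigh_amp_deg: float = 25.0
    gear_ratio: float = 2.5  # wheel revolutions per crank revolution
    wheel_circumference_m: float = 2.1
    lead_frac: float = 0.35  # partial lead-in/out revolutions
    seed: int = 0

    def __post_init__(self):
        if self.n_passive < 1 or self.n_active < 1:
            raise ConfigurationError("n_passive and n_active must be >= 1")
        if self.noise_sd_nm < 0:
            raise ConfigurationError("noise_sd_nm must be >= 0")
        if not (0 <= self.cadence_jitter < 1):
            raise ConfigurationError("cadence_jitter must be in [0, 1)")


def passive_torque_model(
    crank_angle,
    amp1: float = 5.0,
    amp2: float = 1.0,
    offset: float = 0.0,
    phase_deg: float = 0.0,
    side: str = "right",
):
    """Gravity-dominated passive crank torque, per side, in N·m.

    Sum of the first two harmonics of the crank angle; the left leg's
    contribution is shifted half a revolution.  With zero offset the torque
    integrates to zero over a full cycle (gravity is conservative).
    """
    shift = 180.0 if side == "left" else 0.0
    th = np.deg2rad(np.asarray(crank_angle, dtype=float) - phase_deg - shift)
    return -amp1 * np.sin(th) - amp2 * np.sin(2.0 * th) + offset


def _circular_offset(angle, start: float, span: float):
    return np.mod(np.asarray(angle, dtype=float) - start, span)


def active_contribution(
    crank_angle,
    true_interval: StimulationInterval,
    peak: float,
    negative_lobe_fraction: float = 0.0,
):
    """Stimulated-muscle torque as a function of position, in N·m.

    A raised-cosine bump of height ``peak``, strictly positive exactly on
    the open ground-truth interval (wrap-aware) and zero at its endpoints.
    With ``negative_lobe_fraction > 0`` an inverted raised-cosine of depth
    ``negative_lobe_fraction * peak`` fills the rest of the revolution,
    emulating the eccentric resisting action outside the useful range.
    """
    span = true_interval.span
    w = true_interval.width
    u = _circular_offset(crank_angle, true_interval.start, span)
    inside = u < w
    out = np.zeros_like(u)
    out[inside] = peak * np.sin(np.pi * u[inside] / w) ** 2
    if negative_lobe_fraction > 0 and w < span:
        v = u[~inside] - w
        out[~inside] = (
            -negative_lobe_fraction * peak * np.sin(np.pi * v / (span - w)) ** 2
        )
    return out if np.ndim(crank_angle) else float(out)


def thigh_angle_of_crank(crank_angle, config: SimulationConfig, side: str):
    """The simulator's fixed crank-to-thigh geometry."""
    th = np.deg2rad(np.asarray(crank_angle, dtype=float) - THIGH_PHASE_DEG[side])
    return config.thigh_offset_deg + config.thigh_amp_deg * np.cos(th)


def phase_of_crank(crank_angle, side: str):
    """Cycling phase implied by the simulator geometry, in [0, 100).

    With the cosine thigh model and extension mapped to decreasing thigh
    angle, the phase depends only on the crank offset from the flexion
    extremum: ``25 * (1 - cos d)`` on the extension half and
    ``50 + 25 * (1 + cos d)`` on the flexion half.  Useful to map a
    crank-domain ground-truth interval into phase units in tests.
    """
    d = np.mod(np.asarray(crank_angle, dtype=float) - THIGH_PHASE_DEG[side], 360.0)
    rad = np.deg2rad(d)
    ext = d <= 180.0
    out = np.where(ext, 25.0 * (1.0 - np.cos(rad)), 50.0 + 25.0 * (1.0 + np.cos(rad)))
    return np.mod(out, 100.0)


def _crank_trajectory(config: SimulationConfig, rng: np.random.Generator):
    """Piecewise-linear unwrapped crank angle: knot times (ms) and angles."""
    n_cycles = config.n_passive + config.n_active
    cad = config.target_cadence_rpm * (
        1.0 + rng.uniform(-config.cadence_jitter, config.cadence_jitter, n_cycles)
    )
    durations = 60000.0 / cad
    lead = config.lead_frac * 60000.0 / config.target_cadence_rpm
    knots_u = [-config.lead_frac * 360.0, 0.0]
    knots_t = [0.0, lead]
    t = lead
    for d in durations:
        t += d
        knots_t.append(t)
        knots_u.append(knots_u[-1] + 360.0)
    knots_t.append(t + lead)
    knots_u.append(knots_u[-1] + config.lead_frac * 360.0)
    return np.array(knots_t), np.array(knots_u)


def _interp_extrap(x, xp, fp):
    """np.interp with linear extrapolation at both ends."""
    y = np.interp(x, xp, fp)
    lo = x < xp[0]
    hi = x > xp[-1]
    if np.any(lo):
        s = (fp[1] - fp[0]) / (xp[1] - xp[0])
        y[lo] = fp[0] + s * (x[lo] - xp[0])
    if np.any(hi):
        s = (fp[-1] - fp[-2]) / (xp[-1] - xp[-2])
        y[hi] = fp[-1] + s * (x[hi] - xp[-1])
    return y


def simulate_session(config: Optional[SimulationConfig] = None) -> pd.DataFrame:
    """Generate one raw session log as a frame stream.

    The stream starts with a partial lead-in revolution, continues with
    ``n_passive`` unstimulated and ``n_active`` stimulated full revolutions
    (``stim_on`` switches at the crank-cycle boundary) and ends with a
    partial lead-out, so delay alignment can trim the edges without eating a
    full cycle.  Sensor delays are applied: the emitted power-meter channels
    report the state ``delay_sensor_crank`` ms earlier, the thigh channels
    ``delay_sensor_imu`` ms earlier.
    """
    config = config or SimulationConfig()
    rng = np.random.default_rng(config.seed)
    side = CHANNEL_SIDES.get(config.channel, "left")

    knots_t, knots_u = _crank_trajectory(config, rng)
    dt = 1000.0 / config.sample_hz
    n = int(np.floor(knots_t[-1] / dt)) + 1
    t = dt * np.arange(n)

    u_true = _interp_extrap(t, knots_t, knots_u)  # control-time crank angle
    u_pm = _interp_extrap(t - config.delays.delay_sensor_crank, knots_t, knots_u)
    u_imu = _interp_extrap(t - config.delays.delay_sensor_imu, knots_t, knots_u)
    u_act = _interp_extrap(
        t - config.delays.delay_sensor_crank - config.activation_lag_ms,
        knots_t,
        knots_u,
    )

    stim_start_u = 360.0 * config.n_passive
    stim_on = (u_true >= stim_start_u).astype(int)
    # at the instant the power meter *measured* the torque, was stim active?
    stim_at_pm = u_pm >= stim_start_u

    torque = {}
    for s, col in zip(("left", "right"), TORQUE_COLS):
        tau = passive_torque_model(
            u_pm,
            config.passive_amp1_nm,
            config.passive_amp2_nm,
            config.passive_offset_nm,
            config.passive_phase_deg,
            side=s,
        )
        if s == side:
            contrib = active_contribution(
                u_act,
                config.true_interval,
                config.peak_torque_nm,
                config.negative_lobe_fraction,
            )
            tau = tau + np.where(stim_at_pm, contrib, 0.0)
            if config.onset_transient_nm:
                # decaying pulse over the first quarter of the first active cycle
                frac = (u_pm - stim_start_u) / 90.0
                pulse = (frac >= 0) & (frac < 1)
                tau = tau + np.where(
                    pulse,
                    config.onset_transient_nm * np.sin(np.pi * np.clip(frac, 0, 1)) ** 2,
                    0.0,
                )
        if config.noise_sd_nm > 0:
            tau = tau + rng.normal(0.0, config.noise_sd_nm, size=n)
        torque[col] = tau

    frames = pd.DataFrame({TIME_COL: np.round(t).astype(np.int64)})
    frames[CRANK_COL] = np.mod(u_pm, 360.0)
    frames[TORQUE_COLS[0]] = torque[TORQUE_COLS[0]]
    frames[TORQUE_COLS[1]] = torque[TORQUE_COLS[1]]
    for s, col in zip(("left", "right"), THIGH_COLS):
        frames[col] = thigh_angle_of_crank(np.mod(u_imu, 360.0), config, s)
    frames[STIM_COL] = stim_on

    wheel = np.floor(config.gear_ratio * u_true / 360.0)
    events = np.diff(wheel, prepend=wheel[0]) > 0
    frames[WHEEL_COL] = events.astype(int)
    return frames
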