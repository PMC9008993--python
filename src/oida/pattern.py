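"""Cadence-dependent delay compensation, interval membership, the per-sample
stimulation command, and session summary statistics.

Stimulation intervals are detected at a very low cadence, where latency is
negligible; at riding cadence the sensor latency and the muscle's
electromechanical delay each occupy a substantial slice of the revolution.
Stimulation must therefore *start* earlier by

    shift_start = (delay_muscle + delay_sensor) / duration_cycle * span

and *stop* earlier by

    shift_stop = delay_sensor / duration_cycle * span

where ``duration_cycle`` is the current cycle duration in ms and ``span`` is
360 (crank degrees) or 100 (cycling-phase percent).  Only the sensor delay
matters for stopping: by stimulation offset the muscle should stay active
through its electromechanical lag, which is exactly what carries it to the
intended stop position.
"""

from __future__ import annotations

import warnings
from typing import Optional, Union

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .segmentation import (
    PHASE_COLS,
    compute_cycling_phase,
    detect_crank_cycles,
    detect_phase_cycles,
)
from .signals_io import CRANK_COL, TIME_COL, TORQUE_COLS, WHEEL_COL
from .types import (
    CompensatedInterval,
    DelayModel,
    SessionSummary,
    StimulationInterval,
    StimulationPattern,
)


def shift_start(
    delays: DelayModel, duration_cycle: float, span: float = 360.0,
    signal_kind: str = "crank",
) -> float:
    """Position advance of stimulation onset, in domain units."""
    if duration_cycle <= 0:
        raise ValueError("duration_cycle must be > 0")
    return (delays.delay_muscle + delays.sensor_delay(signal_kind)) / duration_cycle * span


def shift_stop(
    delay_sensor: float, duration_cycle: float, span: float = 360.0
) -> float:
    """Position advance of stimulation offset, in domain units."""
    if duration_cycle <= 0:
        raise ValueError("duration_cycle must be > 0")
    return delay_sensor / duration_cycle * span


def compensate_interval(
    interval: StimulationInterval,
    delays: DelayModel,
    duration_cycle: float,
    signal_kind: str = "crank",
) -> CompensatedInterval:
    """Shift an interval's endpoints earlier to compensate latency.

    The start moves back by ``shift_start`` and the stop by ``shift_stop``
    (both modulo the span).  Because the start shifts further than the stop,
    compensation widens the interval; if the compensated width reaches the
    full span the interval saturates to full-cycle and a warning is issued.
    """
    span = interval.span
    s1 = shift_start(delays, duration_cycle, span, signal_kind)
    s2 = shift_stop(delays.sensor_delay(signal_kind), duration_cycle, span)
    if interval.full_cycle:
        return CompensatedInterval(
            0.0, 0.0, span, True, interval, s1, s2
        )
    widened = interval.width + (s1 - s2)
    if widened >= span or s1 >= span:
        warnings.warn(
            "compensated interval covers the full cycle "
            f"(width {widened:.1f} of span {span:g}); saturating",
            stacklevel=2,
        )
        return CompensatedInterval(0.0, 0.0, span, True, interval, s1, s2)
    return CompensatedInterval(
        (interval.start - s1) % span,
        (interval.stop - s2) % span,
        span,
        False,
        interval,
        s1,
        s2,
    )


def in_interval(
    position: Union[float, np.ndarray],
    interval: Union[StimulationInterval, CompensatedInterval],
) -> Union[bool, np.ndarray]:
    """Half-open circular membership: is ``position`` inside the interval?

    ``[start, stop)`` when start < stop; wraps through 0 when start > stop.
    A full-cycle interval contains every position.  Accepts scalars or
    arrays.
    """
    pos = np.asarray(position, dtype=float)
    if interval.full_cycle:
        res = np.ones_like(pos, dtype=bool)
    elif interval.start < interval.stop:
        res = (pos >= interval.start) & (pos < interval.stop)
    else:
        res = (pos >= interval.start) | (pos < interval.stop)
    return bool(res) if np.isscalar(position) else res


def _position_columns(frames: pd.DataFrame, pattern: StimulationPattern) -> pd.DataFrame:
    if pattern.domain == "crank":
        if CRANK_COL not in frames.columns:
            raise ConfigurationError("crank-domain pattern but no crank angle channel")
        return frames
    out = frames
    sides = {ch[0] for ch in pattern.channels}  # 'L'/'R'
    for s in sides:
        side = "left" if s == "L" else "right"
        if PHASE_COLS[side] not in out.columns:
            out = compute_cycling_phase(out, side)
    return out


def stimulation_command(
    frames: pd.DataFrame,
    pattern: StimulationPattern,
    delays: Optional[DelayModel] = None,
    fallback_cadence: float = 30.0,
) -> pd.DataFrame:
    """Replay an aligned stream into per-sample ON/OFF commands per channel.

    For each sample the channel is ON iff its position signal lies inside
    the delay-compensated interval.  The cycle-duration estimate feeding the
    compensation is the duration of the most recently completed cycle of the
    pattern's control signal; before the first cycle completes,
    ``60000 / fallback_cadence`` is used.  Returns a DataFrame with ``t_ms``
    and one boolean column ``cmd_<channel>`` per pattern channel.
    """
    delays = delays or DelayModel()
    frames = _position_columns(frames, pattern)
    t = frames[TIME_COL].to_numpy(dtype=float)
    out = pd.DataFrame({TIME_COL: t})

    for channel, interval in pattern.channels.items():
        side = "left" if channel.startswith("L") else "right"
        if pattern.domain == "crank":
            pos = frames[CRANK_COL].to_numpy(dtype=float)
            cycles = detect_crank_cycles(frames)
        else:
            pos = frames[PHASE_COLS[side]].to_numpy(dtype=float)
            cycles = detect_phase_cycles(frames, side)

        durations = np.full(len(t), 60000.0 / fallback_cadence)
        for prev, cur in zip(cycles[:-1], cycles[1:]):
            durations[(t >= cur.start_t) & (t < cur.end_t)] = prev.duration
        if cycles:
            durations[t >= cycles[-1].end_t] = cycles[-1].duration

        cmd = np.zeros(len(t), dtype=bool)
        valid = ~np.isnan(pos)
        for d in np.unique(durations[valid]):
            comp = compensate_interval(interval, delays, d, pattern.domain)
            sel = valid & (durations == d)
            cmd[sel] = in_interval(pos[sel], comp)
        out[f"cmd_{channel}"] = cmd
    return out


def average_speed_kmh(distance_m: float, duration_s: float) -> float:
    """Average speed in km/h from distance (m) and duration (s)."""
    if duration_s <= 0:
        raise ValueError("duration must be > 0")
    return distance_m / duration_s * 3.6


def summarize_session(
    frames: pd.DataFrame, wheel_circumference: float
) -> SessionSummary:
    """Summary statistics of a cycling session.

    Distance counts rear-wheel revolution events times the wheel
    circumference; average speed is distance over total duration and maximal
    speed the circumference over the shortest inter-event gap.  Cadence and
    power are computed per crank cycle — power as the cycle mean of total
    torque (left + right) times the angular velocity of the unwrapped crank
    angle — and reported as average/maximum over cycles.  Missing source
    channels yield ``None`` fields, never zeros.
    """
    if len(frames) < 2:
        raise ValueError("stream too short to summarize")
    t = frames[TIME_COL].to_numpy(dtype=float)
    duration_s = (t[-1] - t[0]) / 1000.0
    summary = SessionSummary(duration_s=duration_s)

    if WHEEL_COL in frames.columns:
        ev = t[frames[WHEEL_COL].to_numpy() > 0]
        distance = wheel_circumference * len(ev)
        summary.distance_m = distance
        summary.speed_avg_kmh = average_speed_kmh(distance, duration_s)
        if len(ev) >= 2:
            gaps_s = np.diff(ev) / 1000.0
            summary.speed_max_kmh = max(
                wheel_circumference / gaps_s.min() * 3.6, summary.speed_avg_kmh
            )
        elif len(ev) in (0, 1):
            summary.speed_max_kmh = summary.speed_avg_kmh

    cycles = detect_crank_cycles(frames)
    if cycles:
        cadences = np.array([c.cadence for c in cycles])
        powers = []
        for c in cycles:
            ct = c.frames[TIME_COL].to_numpy(dtype=float)
            u = np.unwrap(c.frames[CRANK_COL].to_numpy(dtype=float), period=360.0)
            omega = np.gradient(np.deg2rad(u), ct / 1000.0)  # rad/s
            tau = sum(c.frames[col].to_numpy(dtype=float) for col in TORQUE_COLS)
            powers.append(float(np.mean(tau * omega)))
        powers = np.array(powers)
        summary.cadence_avg_rpm = float(cadences.mean())
        summary.cadence_max_rpm = float(cadences.max())
        summary.power_avg_w = float(powers.mean())
        summary.power_max_w = float(powers.max())
    return summary
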