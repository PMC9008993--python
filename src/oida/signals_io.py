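"""Reading, writing and delay-alignment of multichannel session logs.

The log dialect is a plain comma-separated file with a header row and one
time-stamped sample per line::

    t_ms,crank_angle_deg,torque_left_nm,torque_right_nm,thigh_left_deg,thigh_right_deg[,stim_on][,wheel_rev]

``t_ms`` is integer milliseconds from session start and must be strictly
increasing.  ``crank_angle_deg`` lives on [0, 360): 0 deg is the right
crank-arm pointing vertically down, increasing clockwise seen from the right.
``stim_on`` (0/1) marks samples recorded during continuous stimulation,
``wheel_rev`` (0/1) flags rear-wheel revolution events.

The two sensor families report with different constant latencies (wireless
power meter: crank angle and both torques, ~200 ms; thigh-angle IMUs with
internal Kalman filtering, ~40 ms), so before any cycle analysis the raw
streams are shifted back by their respective delays and resampled onto one
uniform grid (default 100 Hz, the controller rate).
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd

from .errors import AlignmentError, DataError, FormatError
from .types import DelayModel

TIME_COL = "t_ms"
CRANK_COL = "crank_angle_deg"
TORQUE_COLS = ("torque_left_nm", "torque_right_nm")
THIGH_COLS = ("thigh_left_deg", "thigh_right_deg")
STIM_COL = "stim_on"
WHEEL_COL = "wheel_rev"

MANDATORY_COLS = (TIME_COL, CRANK_COL) + TORQUE_COLS + THIGH_COLS
OPTIONAL_COLS = (STIM_COL, WHEEL_COL)

#: Channels carried by the wireless power meter vs. by the IMUs.
POWER_METER_COLS = (CRANK_COL,) + TORQUE_COLS
IMU_COLS = THIGH_COLS


def read_log(path) -> pd.DataFrame:
    """Read a session log, validating the dialect and data invariants.

    Returns a DataFrame with the documented columns.  ``crank_angle_deg`` is
    normalized into [0, 360).  Raises :class:`FormatError` on a missing
    mandatory column and :class:`DataError` (naming the offending row and
    timestamp) when time stamps are not strictly increasing.
    """
    try:
        frames = pd.read_csv(path)
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise FormatError(f"{path}: {exc}") from exc

    missing = [c for c in MANDATORY_COLS if c not in frames.columns]
    if missing:
        raise FormatError(f"{path}: missing mandatory column(s) {missing}")
    unknown = [
        c for c in frames.columns if c not in MANDATORY_COLS + OPTIONAL_COLS
    ]
    if unknown:
        raise FormatError(f"{path}: unknown column(s) {unknown}")

    for col in MANDATORY_COLS:
        bad = frames.index[frames[col].isna()]
        if len(bad):
            # +2: one for the header line, one for 0-based indexing
            raise DataError(
                f"{path}: malformed value in column {col!r} at line {bad[0] + 2}"
            )

    t = frames[TIME_COL].to_numpy(dtype=float)
    dec = np.nonzero(np.diff(t) <= 0)[0]
    if len(dec):
        i = int(dec[0]) + 1
        raise DataError(
            f"{path}: t_ms not strictly increasing at line {i + 2} "
            f"(t={frames[TIME_COL].iloc[i]} ms)"
        )

    frames[CRANK_COL] = np.mod(frames[CRANK_COL].to_numpy(dtype=float), 360.0)
    for col in OPTIONAL_COLS:
        if col in frames.columns:
            frames[col] = frames[col].fillna(0).astype(int)
    return frames


def write_log(frames: pd.DataFrame, path) -> None:
    """Write a frame stream in the documented CSV dialect.

    ``write_log(read_log(p), p2)`` reproduces the file up to float
    formatting (full round-trip precision is kept).
    """
    out = frames.copy()
    out[TIME_COL] = out[TIME_COL].astype(np.int64)
    out.to_csv(path, index=False)


def _step_interp(tq: np.ndarray, t: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Previous-value (zero-order hold) interpolation for flag channels."""
    idx = np.searchsorted(t, tq, side="right") - 1
    idx = np.clip(idx, 0, len(t) - 1)
    return v[idx]


def align_streams(
    frames: pd.DataFrame,
    delays: Optional[DelayModel] = None,
    grid_hz: float = 100.0,
) -> pd.DataFrame:
    """Undo per-sensor transmission delays and resample onto a uniform grid.

    A sample reported at time ``t`` reflects the physical state ``delay`` ms
    earlier, so power-meter channels are shifted to ``t - delay_sensor_crank``
    and IMU channels to ``t - delay_sensor_imu`` before all channels are
    linearly interpolated onto one grid with spacing ``1000 / grid_hz`` ms.
    The crank angle is unwrapped before interpolation and re-wrapped to
    [0, 360) after, so interpolation never jumps across the 360->0 seam.
    Only the time range covered by every shifted channel is kept (no
    extrapolation): the head/tail of the session shorter than the largest
    delay is dropped.
    """
    if delays is None:
        delays = DelayModel()
    if grid_hz <= 0:
        raise AlignmentError("grid_hz must be > 0")
    if len(frames) < 2:
        raise AlignmentError("stream too short to align")

    t = frames[TIME_COL].to_numpy(dtype=float)
    span = t[-1] - t[0]
    largest = max(delays.delay_sensor_crank, delays.delay_sensor_imu)
    if span <= largest:
        raise AlignmentError(
            f"stream spans {span:.0f} ms, shorter than the largest sensor "
            f"delay ({largest:.0f} ms)"
        )

    t_pm = t - delays.delay_sensor_crank
    t_imu = t - delays.delay_sensor_imu
    dt = 1000.0 / grid_hz
    t0 = max(t_pm[0], t_imu[0], t[0] if _has_flags(frames) else -np.inf)
    t1 = min(t_pm[-1], t_imu[-1], t[-1] if _has_flags(frames) else np.inf)
    g0 = np.ceil(t0 / dt) * dt
    n = int(np.floor((t1 - g0) / dt)) + 1
    if n < 2:
        raise AlignmentError("aligned overlap of the channels is too short")
    grid = g0 + dt * np.arange(n)

    out = pd.DataFrame({TIME_COL: grid})
    unwrapped = np.unwrap(frames[CRANK_COL].to_numpy(dtype=float), period=360.0)
    out[CRANK_COL] = np.mod(np.interp(grid, t_pm, unwrapped), 360.0)
    for col in TORQUE_COLS:
        out[col] = np.interp(grid, t_pm, frames[col].to_numpy(dtype=float))
    for col in IMU_COLS:
        out[col] = np.interp(grid, t_imu, frames[col].to_numpy(dtype=float))

    if STIM_COL in frames.columns:
        out[STIM_COL] = _step_interp(
            grid, t, frames[STIM_COL].to_numpy(dtype=float)
        ).astype(int)
    if WHEEL_COL in frames.columns:
        flags = np.zeros(len(grid), dtype=int)
        for te in t[frames[WHEEL_COL].to_numpy() > 0]:
            if grid[0] - dt / 2 <= te <= grid[-1] + dt / 2:
                flags[int(round((te - grid[0]) / dt))] = 1
        out[WHEEL_COL] = flags
    return out


def _has_flags(frames: pd.DataFrame) -> bool:
    return any(c in frames.columns for c in OPTIONAL_COLS)
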