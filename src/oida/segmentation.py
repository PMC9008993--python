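"""Cycle detection, cadence gating, and the IMU-based cycling phase.

Two position signals can drive the system: the crank angle itself, or the
*cycling phase* — a per-leg normalization of the thigh angle onto [0, 100) in
which 0–50 % is knee extension and 50–100 % knee flexion, with the extremal
thigh angles of the most recently completed cycle serving as the
normalization anchors.  Cycles are gated by cadence: a cycle is accepted only
when its cadence lies within ``target * (1 +- tolerance)`` (bounds inclusive;
rejection is strict).
"""

from __future__ import annotations

from typing import List, Optional

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .errors import DegenerateMotionError
from .signals_io import CRANK_COL, TIME_COL
from .types import Cycle

PHASE_COLS = {"left": "phase_left_pct", "right": "phase_right_pct"}

#: Confirmation margin (deg) a crossing of a cycle boundary must be exceeded
#: by before the boundary is accepted; guards against angle jitter at 0 deg.
HYSTERESIS_DEG = 5.0


def _crossing_times(t: np.ndarray, u: np.ndarray, hysteresis: float) -> List[float]:
    """Interpolated times of the first upward crossing of each 360k level.

    ``u`` is the unwrapped crank angle.  For each level 360*k strictly inside
    the travelled range, the first sample pair bracketing the level from
    below is taken — later re-crossings of the same level (backward jitter)
    are ignored — and the crossing is only confirmed once the signal has
    advanced ``hysteresis`` degrees beyond the level.
    """
    lo, hi = u.min(), u.max()
    k0 = int(np.floor(lo / 360.0)) + 1
    k1 = int(np.ceil(hi / 360.0)) - 1
    times = []
    for k in range(k0, k1 + 1):
        level = 360.0 * k
        below = u[:-1] < level
        above = u[1:] >= level
        idx = np.nonzero(below & above)[0]
        for i in idx:
            if np.max(u[i + 1:]) >= level + hysteresis:
                frac = (level - u[i]) / (u[i + 1] - u[i])
                times.append(t[i] + frac * (t[i + 1] - t[i]))
                break
    return sorted(times)


def detect_crank_cycles(
    frames: pd.DataFrame, hysteresis_deg: float = HYSTERESIS_DEG
) -> List[Cycle]:
    """Segment an aligned stream into full crank revolutions.

    A cycle boundary is the (linearly interpolated) upward crossing of the
    crank angle through 0 deg; partial head/tail revolutions are discarded.
    Returns an empty list when less than one full revolution is present.
    """
    if len(frames) < 2:
        return []
    t = frames[TIME_COL].to_numpy(dtype=float)
    u = np.unwrap(frames[CRANK_COL].to_numpy(dtype=float), period=360.0)
    if u[-1] < u[0]:  # pedalling direction reversed relative to convention
        u = -u
    times = _crossing_times(t, u, hysteresis_deg)
    cycles = []
    for a, b in zip(times[:-1], times[1:]):
        sel = frames[(frames[TIME_COL] >= a) & (frames[TIME_COL] < b)]
        if len(sel) >= 2:
            cycles.append(Cycle(frames=sel, start_t=a, end_t=b, kind="crank"))
    return cycles


def compute_cycling_phase(
    frames: pd.DataFrame,
    side: str,
    min_range_deg: float = 10.0,
    extension_decreasing: bool = True,
) -> pd.DataFrame:
    """Normalize one leg's thigh angle into the cycling phase [0, 100).

    A cycle runs from one full-flexion extremum to the next.  Within the
    extension half the phase is ``50 * (theta - theta_flex) / (theta_ext -
    theta_flex)`` (0 at full flexion, 50 at full extension) and within the
    flexion half ``50 + 50 * (theta_ext - theta) / (theta_ext - theta_flex)``.
    The anchors ``theta_flex`` / ``theta_ext`` are the extrema of the most
    recently completed cycle; the first cycle uses its own extrema and is
    emitted retrospectively.  ``extension_decreasing`` states whether knee
    extension corresponds to a decreasing raw thigh angle (mounting
    dependent).

    Returns ``frames`` with an added column ``phase_{side}_pct``; samples
    outside any complete cycle are NaN.  Raises
    :class:`DegenerateMotionError` when the thigh-angle range is below
    ``min_range_deg``.
    """
    col = {"left": "thigh_left_deg", "right": "thigh_right_deg"}[side]
    theta = frames[col].to_numpy(dtype=float)
    if np.ptp(theta) < min_range_deg:
        raise DegenerateMotionError(
            f"thigh angle range {np.ptp(theta):.1f} deg < {min_range_deg} deg"
        )

    sign = 1.0 if extension_decreasing else -1.0
    s = sign * theta  # flexion extrema are maxima of s
    prominence = min_range_deg / 2.0
    flex_idx, _ = find_peaks(s, prominence=prominence)
    ext_idx, _ = find_peaks(-s, prominence=prominence)

    phase = np.full(len(theta), np.nan)
    prev_flex_val: Optional[float] = None
    prev_ext_val: Optional[float] = None
    for j in range(len(flex_idx) - 1):
        a, b = flex_idx[j], flex_idx[j + 1]
        mids = ext_idx[(ext_idx > a) & (ext_idx < b)]
        if len(mids) == 0:
            continue
        m = mids[int(np.argmin(s[mids]))]
        own_flex, own_ext = theta[a], theta[m]
        th_flex = own_flex if prev_flex_val is None else theta[a]
        th_ext = own_ext if prev_ext_val is None else prev_ext_val
        if abs(th_ext - th_flex) < min_range_deg:
            th_flex, th_ext = own_flex, own_ext
        denom = th_ext - th_flex
        ext_limb = 50.0 * (theta[a:m] - th_flex) / denom
        flex_limb = 50.0 + 50.0 * (th_ext - theta[m:b]) / denom
        phase[a:m] = np.clip(ext_limb, 0.0, 50.0)
        phase[m:b] = np.clip(flex_limb, 50.0, np.nextafter(100.0, 0.0))
        prev_flex_val, prev_ext_val = own_flex, own_ext

    out = frames.copy()
    out[PHASE_COLS[side]] = phase
    return out


def detect_phase_cycles(frames: pd.DataFrame, side: str) -> List[Cycle]:
    """Segment a phase stream into full flexion-extension-flexion cycles.

    Boundaries are the wrap of the phase through 100 -> 0 (interpolated in
    the unwrapped phase); partial head/tail cycles are discarded.
    """
    col = PHASE_COLS[side]
    t = frames[TIME_COL].to_numpy(dtype=float)
    p = frames[col].to_numpy(dtype=float)
    times = []
    for i in range(len(p) - 1):
        if np.isnan(p[i]) or np.isnan(p[i + 1]):
            continue
        if p[i + 1] < p[i] - 50.0:  # wrapped
            up_next = p[i + 1] + 100.0
            frac = (100.0 - p[i]) / (up_next - p[i])
            times.append(t[i] + frac * (t[i + 1] - t[i]))
        elif p[i] == 0.0 and i > 0 and np.isnan(p[i - 1]):
            times.append(t[i])  # first cycle starts at its own extremum
    # the first complete cycle begins where the phase first becomes defined
    valid = np.nonzero(~np.isnan(p))[0]
    if len(valid) and (not times or t[valid[0]] < times[0]):
        times.insert(0, t[valid[0]])
    # ... and the last one ends where it last is
    if len(valid) and valid[-1] == len(p) - 1:
        pass  # stream ends mid-cycle; tail cycle has no closing boundary
    elif len(valid):
        times.append(t[valid[-1] + 1])
    times = sorted(set(times))
    cycles = []
    for a, b in zip(times[:-1], times[1:]):
        sel = frames[(frames[TIME_COL] >= a) & (frames[TIME_COL] < b)]
        if len(sel) >= 2 and not sel[col].isna().any():
            cycles.append(Cycle(frames=sel, start_t=a, end_t=b, kind="phase", side=side))
    return cycles


def validate_cadence(cycle: Cycle, target_cadence: float, tolerance: float) -> bool:
    """Accept a cycle iff its cadence lies within target * (1 +- tolerance).

    Bounds are inclusive: with the default target of 5 RPM and 50 %
    tolerance, cycles are rejected strictly above 7.5 or strictly below
    2.5 RPM.
    """
    if target_cadence <= 0 or not (0 < tolerance < 1):
        raise ValueError("need target_cadence > 0 and tolerance in (0, 1)")
    lo = target_cadence * (1.0 - tolerance)
    hi = target_cadence * (1.0 + tolerance)
    return lo <= cycle.cadence <= hi
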