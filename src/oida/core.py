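"""Optimal stimulation-interval detection from passive/active torque cycles.

The method: record a set of *passive* pedalling cycles (leg moved by the
examiner, no stimulation) and a set of *active* cycles (continuous
stimulation of one muscle channel), both at a slow target cadence.  Each
accepted cycle's torque is re-expressed as a function of position (crank
angle or cycling phase) on a fixed template vector — 0–360 deg in 1 deg
steps, or 0–100 % in 1 % steps — which removes any dependence on the
instantaneous angular velocity.  The per-set mean profiles are subtracted
(net torque = active − passive); positions of positive net torque are where
the stimulated muscle helps the motion.  The optimal stimulation interval is
the contiguous (circular) run of positive net torque containing the global
maximum, found by walking outward from the peak to the nearest
zero-transitions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import (
    ConfigurationError,
    DomainMismatchError,
    InsufficientCyclesError,
    NoPositiveContributionError,
    SparseCycleError,
)
from .segmentation import (
    PHASE_COLS,
    compute_cycling_phase,
    detect_crank_cycles,
    detect_phase_cycles,
    validate_cadence,
)
from .signals_io import CRANK_COL, STIM_COL, TIME_COL, align_streams
from .types import (
    Cycle,
    DelayModel,
    NetTorqueProfile,
    SessionConfig,
    StimulationInterval,
    TorqueProfile,
    domain_bins,
    domain_span,
)

#: Largest tolerated gap (in template bins) between consecutive position
#: samples of a cycle before it is considered too sparse to normalize.
MAX_GAP_BINS = 20

TORQUE_BY_SIDE = {"left": "torque_left_nm", "right": "torque_right_nm"}


def _cycle_positions(cycle: Cycle, domain: str) -> np.ndarray:
    """Position of each frame within the cycle, in [0, span]."""
    if domain == "crank":
        ang = cycle.frames[CRANK_COL].to_numpy(dtype=float)
        u = np.unwrap(ang, period=360.0)
        # re-anchor so the first sample (just past the 0-deg boundary) is
        # near 0; small negative jitter is clamped below
        u -= 360.0 * np.floor((u[0] + 180.0) / 360.0)
        return u
    if domain == "phase":
        if cycle.side is None:
            raise ConfigurationError("phase cycle without a side")
        return cycle.frames[PHASE_COLS[cycle.side]].to_numpy(dtype=float)
    raise DomainMismatchError(f"unknown domain {domain!r}")


def normalize_cycle(
    cycle: Cycle,
    torque_side: str,
    domain: Optional[str] = None,
    max_gap_bins: int = MAX_GAP_BINS,
) -> TorqueProfile:
    """Resample one cycle's torque onto the template vector.

    Torque is linearly interpolated at each template bin *as a function of
    position*, not of time, so cycles recorded at different (and varying)
    cadences land on the same axis.  Raises :class:`SparseCycleError` when
    the position samples leave a gap wider than ``max_gap_bins`` bins
    anywhere on the domain (edges included).
    """
    domain = domain or cycle.kind
    span = domain_span(domain)
    nbins = domain_bins(domain)
    pos = np.clip(_cycle_positions(cycle, domain), 0.0, span)
    tau = cycle.frames[TORQUE_BY_SIDE[torque_side]].to_numpy(dtype=float)
    if len(pos) < 2:
        raise SparseCycleError("cycle has fewer than 2 frames")

    order = np.argsort(pos, kind="stable")
    pos, tau = pos[order], tau[order]
    bin_width = span / (nbins - 1)
    gaps = np.diff(np.concatenate(([0.0], pos, [span])))
    if gaps.max() > max_gap_bins * bin_width:
        raise SparseCycleError(
            f"position gap of {gaps.max():.1f} exceeds {max_gap_bins} bins"
        )

    bins = np.linspace(0.0, span, nbins)
    values = np.interp(bins, pos, tau)
    # bin 0 and bin span are the same physical position on the circle
    seam = 0.5 * (values[0] + values[-1])
    values[0] = values[-1] = seam
    return TorqueProfile(domain=domain, values=values, n_cycles_averaged=1)


def average_profiles(profiles: Sequence[TorqueProfile]) -> TorqueProfile:
    """Per-bin arithmetic mean of same-domain profiles."""
    if not profiles:
        raise ValueError("need at least one profile")
    domain = profiles[0].domain
    if any(p.domain != domain for p in profiles):
        raise DomainMismatchError("cannot average profiles on mixed domains")
    values = np.mean([p.values for p in profiles], axis=0)
    n = sum(p.n_cycles_averaged for p in profiles)
    return TorqueProfile(domain=domain, values=values, n_cycles_averaged=n)


def net_torque(active_mean: TorqueProfile, passive_mean: TorqueProfile) -> NetTorqueProfile:
    """Net torque profile: active mean minus passive mean, bin by bin."""
    if active_mean.domain != passive_mean.domain:
        raise DomainMismatchError("active/passive profiles on different domains")
    return NetTorqueProfile(
        domain=active_mean.domain,
        values=active_mean.values - passive_mean.values,
        n_cycles_averaged=active_mean.n_cycles_averaged,
        n_active=active_mean.n_cycles_averaged,
        n_passive=passive_mean.n_cycles_averaged,
    )


def _circular_values(net: TorqueProfile, smooth_window: Optional[int]) -> np.ndarray:
    # drop the duplicated seam bin: bins 0..span-1 represent the circle
    c = net.values[:-1].copy()
    if smooth_window and smooth_window > 1:
        k = np.ones(smooth_window) / smooth_window
        c = np.convolve(np.concatenate((c, c, c)), k, mode="same")[len(c):2 * len(c)]
    return c


def detect_optimal_interval(
    net: TorqueProfile, smooth_window: Optional[int] = None
) -> StimulationInterval:
    """Find the optimal stimulation interval on a net-torque profile.

    Locates the bin of maximal net torque (ties broken towards bin 0), then
    walks circularly backward/forward to the nearest zero-transitions: the
    interval start is the first positive bin of the run containing the
    maximum and the stop the bin just past its last positive bin, at integer
    bin resolution.  Every bin inside [start, stop) has net torque > 0.

    Raises :class:`NoPositiveContributionError` when the net torque never
    becomes positive; returns a full-cycle interval (flagged) when it is
    positive everywhere.  ``smooth_window`` optionally applies a circular
    moving average before the search (off by default).
    """
    c = _circular_values(net, smooth_window)
    n = len(c)
    imax = int(np.argmax(c))
    if c[imax] <= 0:
        raise NoPositiveContributionError(
            f"maximal net torque {c[imax]:.3f} N·m is not positive"
        )
    if np.all(c > 0):
        return StimulationInterval(0.0, 0.0, span=float(n), full_cycle=True)

    i = imax
    while c[(i - 1) % n] > 0:
        i -= 1
    j = imax
    while c[(j + 1) % n] > 0:
        j += 1
    start = i % n
    stop = (j + 1) % n
    return StimulationInterval(float(start), float(stop), span=float(n))


@dataclass
class OidaResult:
    """Everything produced by one interval-detection run."""

    interval: StimulationInterval
    channel: str
    domain: str
    passive_profile: TorqueProfile
    active_profile: TorqueProfile
    net_profile: NetTorqueProfile
    cycle_report: pd.DataFrame = field(repr=False)
    """Per-cycle diagnostics: phase (passive/active), start/end time, cadence,
    accepted flag, used flag (first accepted active cycle is never used)."""


def _split_time(aligned: pd.DataFrame, split_t: Optional[float]) -> float:
    if STIM_COL in aligned.columns and aligned[STIM_COL].any():
        return float(aligned.loc[aligned[STIM_COL] > 0, TIME_COL].iloc[0])
    if split_t is None:
        raise ConfigurationError(
            "no stim_on flags in the log and no explicit split time given"
        )
    return float(split_t)


def run_oida(
    frames: pd.DataFrame,
    config: SessionConfig,
    delays: Optional[DelayModel] = None,
    split_t: Optional[float] = None,
    grid_hz: float = 100.0,
    smooth_window: Optional[int] = None,
) -> OidaResult:
    """Run the full detection pipeline on a raw session log.

    The log must contain a passive segment followed by an active
    (stimulated) segment, separated either by ``stim_on`` flags or by an
    explicit ``split_t`` (ms).  Streams are delay-aligned, segmented into
    cycles of the configured control signal, cadence-gated, and the first
    accepted active cycle is discarded (the sudden movement at stimulation
    onset makes it unrepresentative).  ``config.n_cycles`` accepted cycles
    per set are then normalized, averaged and differenced, and the optimal
    interval is located on the net profile.
    """
    delays = delays or DelayModel()
    aligned = align_streams(frames, delays, grid_hz=grid_hz)
    t_on = _split_time(aligned, split_t)

    if config.signal_kind == "phase":
        aligned = compute_cycling_phase(aligned, config.side)
        cycles = detect_phase_cycles(aligned, config.side)
    else:
        cycles = detect_crank_cycles(aligned)

    # the stim_on flag switches at the first sample *after* the true onset,
    # so allow cycle boundaries within 1.5 grid steps of the switch
    tol = 1.5 * 1000.0 / grid_hz
    passive: List[Cycle] = []
    active: List[Cycle] = []
    report_rows = []
    for cyc in cycles:
        if cyc.end_t <= t_on + tol:
            phase_name = "passive"
        elif cyc.start_t >= t_on - tol:
            phase_name = "active"
        else:
            continue  # straddles the stimulation switch
        ok = validate_cadence(cyc, config.target_cadence_rpm, config.cadence_tolerance)
        report_rows.append(
            {
                "phase": phase_name,
                "start_t_ms": cyc.start_t,
                "end_t_ms": cyc.end_t,
                "cadence_rpm": cyc.cadence,
                "accepted": ok,
                "used": False,
            }
        )
        if ok:
            (passive if phase_name == "passive" else active).append(cyc)

    # first accepted active cycle: stimulation-onset transient, never used
    active_usable = active[1:]
    if len(passive) < config.n_cycles:
        raise InsufficientCyclesError("passive", len(passive), config.n_cycles)
    if len(active_usable) < config.n_cycles:
        raise InsufficientCyclesError("active", len(active_usable), config.n_cycles)
    passive_used = passive[: config.n_cycles]
    active_used = active_usable[: config.n_cycles]

    report = pd.DataFrame(report_rows)
    used_starts = {c.start_t for c in passive_used} | {c.start_t for c in active_used}
    if len(report):
        report["used"] = report["start_t_ms"].isin(used_starts) & report["accepted"]

    domain = config.signal_kind
    passive_mean = average_profiles(
        [normalize_cycle(c, config.side, domain) for c in passive_used]
    )
    active_mean = average_profiles(
        [normalize_cycle(c, config.side, domain) for c in active_used]
    )
    net = net_torque(active_mean, passive_mean)
    interval = detect_optimal_interval(net, smooth_window=smooth_window)
    return OidaResult(
        interval=interval,
        channel=config.channel,
        domain=domain,
        passive_profile=passive_mean,
        active_profile=active_mean,
        net_profile=net,
        cycle_report=report,
    )
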