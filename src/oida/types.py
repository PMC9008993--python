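"""Core domain types shared across the package.

Sensor streams are represented as :class:`pandas.DataFrame` objects with the
column names defined in :mod:`oida.signals_io`; the small value types below
(delays, intervals, configuration, cycles, torque profiles) are plain
dataclasses.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from datetime import datetime, timezone
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError, DomainMismatchError

#: Template bin counts: crank angle 0..360 deg in 1 deg steps, cycling phase
#: 0..100 % in 1 % steps.  The first and last bin are the same physical
#: position on the circle.
CRANK_BINS = 361
PHASE_BINS = 101

CRANK_SPAN = 360.0
PHASE_SPAN = 100.0

#: Muscle channel -> body side.  LQ/RQ = left/right quadriceps,
#: LH/RH = left/right hamstrings.
CHANNEL_SIDES = {"LQ": "left", "RQ": "right", "LH": "left", "RH": "right"}


def domain_span(domain: str) -> float:
    if domain == "crank":
        return CRANK_SPAN
    if domain == "phase":
        return PHASE_SPAN
    raise DomainMismatchError(f"unknown domain {domain!r}")


def domain_bins(domain: str) -> int:
    return CRANK_BINS if domain == "crank" else PHASE_BINS


@dataclass(frozen=True)
class DelayModel:
    """Constant transmission/processing latencies of the system, in ms.

    ``delay_sensor_crank`` is the wireless power-meter latency affecting the
    crank-angle and both torque channels; ``delay_sensor_imu`` the IMU Kalman
    filter latency affecting the thigh angles; ``delay_muscle`` the
    electromechanical delay between stimulation onset and force production.
    """

    delay_sensor_crank: float = 200.0
    delay_sensor_imu: float = 40.0
    delay_muscle: float = 200.0

    def __post_init__(self):
        for name in ("delay_sensor_crank", "delay_sensor_imu", "delay_muscle"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")

    def sensor_delay(self, signal_kind: str) -> float:
        """Sensor latency of the position signal used for control."""
        if signal_kind == "crank":
            return self.delay_sensor_crank
        if signal_kind == "phase":
            return self.delay_sensor_imu
        raise ConfigurationError(f"unknown signal kind {signal_kind!r}")

    @classmethod
    def from_yaml(cls, path) -> "DelayModel":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


@dataclass
class SessionConfig:
    """Parameters of one interval-detection session.

    Defaults follow the measurement protocol: biphasic pulses of 400 us at
    72 mA and 40 Hz, 3 cycles averaged per (passive/active) set, target
    cadence 5 RPM with a +-50 % acceptance tolerance.
    """

    channel: str = "LQ"
    stim_frequency_hz: float = 40.0
    stim_amplitude_ma: float = 72.0
    stim_phasewidth_us: float = 400.0
    n_cycles: int = 3
    target_cadence_rpm: float = 5.0
    cadence_tolerance: float = 0.5
    signal_kind: str = "crank"
    side: Optional[str] = None  # derived from channel when None

    def __post_init__(self):
        if self.n_cycles < 1:
            raise ConfigurationError("n_cycles must be >= 1")
        if not (0 < self.cadence_tolerance < 1):
            raise ConfigurationError("cadence_tolerance must be in (0, 1)")
        if self.target_cadence_rpm <= 0:
            raise ConfigurationError("target_cadence_rpm must be > 0")
        if self.signal_kind not in ("crank", "phase"):
            raise ConfigurationError("signal_kind must be 'crank' or 'phase'")
        if self.side is None:
            self.side = CHANNEL_SIDES.get(self.channel)
        if self.side not in ("left", "right"):
            raise ConfigurationError(
                f"side could not be derived from channel {self.channel!r}; "
                "pass side='left'|'right' explicitly"
            )

    @classmethod
    def from_yaml(cls, path) -> "SessionConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


@dataclass
class Cycle:
    """One full pedalling revolution (crank) or one flexion-extension-flexion
    thigh cycle (phase), with the aligned frames it spans."""

    frames: pd.DataFrame
    start_t: float
    end_t: float
    kind: str  # "crank" | "phase"
    side: Optional[str] = None  # phase cycles only

    def __post_init__(self):
        if self.end_t <= self.start_t:
            raise ValueError("cycle must have positive duration")

    @property
    def duration(self) -> float:
        """Cycle duration in ms."""
        return self.end_t - self.start_t

    @property
    def cadence(self) -> float:
        """Cadence in RPM (60000 / duration)."""
        return 60000.0 / self.duration


@dataclass
class TorqueProfile:
    """Torque resampled onto the fixed template vector.

    ``values`` has 361 entries for the crank domain (bins 0..360 deg) or 101
    for the phase domain (bins 0..100 %); first and last bin refer to the same
    physical position and carry the same value.
    """

    domain: str
    values: np.ndarray
    n_cycles_averaged: int = 1

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        expected = domain_bins(self.domain)
        if self.values.shape != (expected,):
            raise DomainMismatchError(
                f"{self.domain} profile needs {expected} bins, got {self.values.shape}"
            )
        if np.isnan(self.values).any():
            raise ValueError("profile contains missing bins")

    @property
    def span(self) -> float:
        return domain_span(self.domain)

    @property
    def bins(self) -> np.ndarray:
        return np.arange(domain_bins(self.domain), dtype=float)


@dataclass
class NetTorqueProfile(TorqueProfile):
    """Active minus passive mean torque, on the same template."""

    n_passive: int = 0
    n_active: int = 0


@dataclass(frozen=True)
class StimulationInterval:
    """Circular start/stop of one stimulation channel, in domain units.

    ``start`` may exceed ``stop``, in which case the interval wraps through 0.
    ``full_cycle`` marks an interval covering the whole revolution (start and
    stop are then both 0 by convention).
    """

    start: float
    stop: float
    span: float = CRANK_SPAN
    full_cycle: bool = False

    def __post_init__(self):
        if not (0 <= self.start < self.span and 0 <= self.stop < self.span):
            raise ValueError("start/stop must lie in [0, span)")
        if not self.full_cycle and self.start == self.stop:
            raise ValueError("start == stop only allowed with full_cycle=True")

    @property
    def width(self) -> float:
        """Circular width of the interval in domain units."""
        if self.full_cycle:
            return self.span
        return (self.stop - self.start) % self.span


@dataclass(frozen=True)
class CompensatedInterval:
    """A stimulation interval after cadence-dependent delay compensation."""

    start: float
    stop: float
    span: float
    full_cycle: bool
    source: StimulationInterval
    shift_start: float
    shift_stop: float

    def as_interval(self) -> StimulationInterval:
        return StimulationInterval(
            self.start, self.stop, span=self.span, full_cycle=self.full_cycle
        )


@dataclass
class StimulationPattern:
    """Mapping of muscle channels to their stimulation intervals on one
    control-signal domain."""

    domain: str
    channels: dict  # channel id -> StimulationInterval
    n_cycles: int = 0
    generated_at: str = field(
        default_factory=lambda: datetime.now(timezone.utc).isoformat(timespec="seconds")
    )

    def to_json(self, path) -> None:
        payload = {
            "domain": self.domain,
            "span": domain_span(self.domain),
            "n_cycles": self.n_cycles,
            "generated_at": self.generated_at,
            "channels": {
                ch: {
                    "start": iv.start,
                    "stop": iv.stop,
                    "full_cycle": iv.full_cycle,
                }
                for ch, iv in self.channels.items()
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "StimulationPattern":
        with open(path) as fh:
            payload = json.load(fh)
        span = domain_span(payload["domain"])
        channels = {
            ch: StimulationInterval(
                d["start"], d["stop"], span=span, full_cycle=d.get("full_cycle", False)
            )
            for ch, d in payload["channels"].items()
        }
        return cls(
            domain=payload["domain"],
            channels=channels,
            n_cycles=payload.get("n_cycles", 0),
            generated_at=payload.get("generated_at", ""),
        )


@dataclass
class SessionSummary:
    """Summary statistics of a cycling session.

    Quantities whose source channel is missing are ``None`` (never silently
    zero).  Speeds in km/h, cadence in RPM, power in W, distance in m.
    """

    duration_s: float
    distance_m: Optional[float] = None
    speed_avg_kmh: Optional[float] = None
    speed_max_kmh: Optional[float] = None
    cadence_avg_rpm: Optional[float] = None
    cadence_max_rpm: Optional[float] = None
    power_avg_w: Optional[float] = None
    power_max_w: Optional[float] = None

    @property
    def duration_mmss(self) -> str:
        m, s = divmod(int(round(self.duration_s)), 60)
        return f"{m:02d}:{s:02d}"
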