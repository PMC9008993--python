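"""Exception hierarchy for the oida package."""


class OidaError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(OidaError):
    """A log file does not conform to the documented CSV dialect."""


class DataError(OidaError):
    """A log file is syntactically valid but violates a data invariant."""


class AlignmentError(OidaError):
    """A stream is too short (or otherwise unusable) for delay alignment."""


class SparseCycleError(OidaError):
    """A cycle's position samples leave a gap wider than the allowed maximum."""


class DomainMismatchError(OidaError):
    """Profiles on different template domains were combined."""


class DegenerateMotionError(OidaError):
    """Thigh-angle range is too small to define a cycling phase."""


class NoPositiveContributionError(OidaError):
    """The net torque never becomes positive: the muscle never contributes."""


class InsufficientCyclesError(OidaError):
    """Fewer accepted cycles than required by the session configuration."""

    def __init__(self, phase: str, accepted: int, required: int):
        self.phase = phase
        self.accepted = accepted
        self.required = required
        super().__init__(f"{phase}: {accepted}/{required} accepted cycles")


class ConfigurationError(OidaError):
    """Inconsistent or incomplete configuration."""
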