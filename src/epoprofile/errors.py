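"""Exception hierarchy.

All package-specific failures derive from :class:`EpoProfileError` so callers
can catch one base class; subclasses mirror the failure modes of the
pipeline stages (input validation, generator configuration, band detection,
region calibration, profile classification).
"""


class EpoProfileError(Exception):
    """Base class for all errors raised by epoprofile."""


class InvalidInputError(EpoProfileError, ValueError):
    """An input value violates a documented precondition."""


class ConfigurationError(EpoProfileError, ValueError):
    """Generator or analysis parameters are inconsistent or infeasible."""


class NoBandsError(EpoProfileError):
    """No peak in a lane passed the detection thresholds."""

    def __init__(self, lane_id: str, message: str | None = None):
        self.lane_id = lane_id
        super().__init__(message or f"no bands detected in lane {lane_id!r}")


class InsufficientBandsError(EpoProfileError):
    """Fewer than three bands available for top-3 selection."""


class CalibrationError(EpoProfileError):
    """Reference lanes do not define a valid acidic/neutral/basic partition."""


class ClassificationError(EpoProfileError):
    """A lane cannot be assigned a profile class."""
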