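"""Exception hierarchy shared across the pipeline.

Validation errors signal bad user input (exit code 2 in scripts); numerical
errors signal solver failure (exit code 3).
"""


class MechanomapError(Exception):
    """Base class for all package errors."""


class ValidationError(MechanomapError, ValueError):
    """Invalid parameter or precondition violation."""


class CapacityError(ValidationError):
    """A requested synthetic scene does not fit the available volume."""


class SignalRangeError(ValidationError):
    """A signal value lies outside the attainable range of the calibration model."""


class BoundaryError(ValidationError):
    """An ROI window would extend past the volume boundary."""


class ScheduleRangeError(ValidationError):
    """A loading profile was evaluated outside its schedule."""


class WindowError(ValidationError):
    """A requested time window is not covered by a trajectory."""


class DegenerateCloudError(ValidationError):
    """A point cloud is too degenerate (e.g. collinear) for registration."""


class PLYParseError(MechanomapError):
    """A point-cloud file could not be parsed."""


class NumericalError(MechanomapError, RuntimeError):
    """A numerical routine failed to converge."""


class FitError(NumericalError):
    """Nonlinear least-squares calibration fit failed."""
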