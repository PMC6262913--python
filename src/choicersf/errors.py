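"""Exception hierarchy for the choicersf pipeline.

Every stage raises a subclass of :class:`ChoicersfError`, so batch drivers
can catch one type, mark the individual as failed, and keep going.
"""


class ChoicersfError(Exception):
    """Base class for all package errors."""


class InvalidConfigError(ChoicersfError):
    """A configuration value violates its contract (e.g. non-PSD correlation)."""


class InvalidInputError(ChoicersfError):
    """Runtime input violates a precondition (e.g. point outside the grid)."""


class InvalidTrackError(InvalidInputError):
    """A telemetry track is malformed (non-increasing timestamps, zero gaps)."""


class InsufficientDataError(ChoicersfError):
    """Too few observations to compute the requested quantity."""


class DegenerateTrackError(ChoicersfError):
    """Movement statistics imply a non-positive availability radius."""


class SamplingFailedError(ChoicersfError):
    """Rejection sampling of available points exhausted its retry budget."""

    def __init__(self, message: str, fix_index: int | None = None):
        super().__init__(message)
        self.fix_index = fix_index


class SimulationStuckError(SamplingFailedError):
    """Track simulation could not place a candidate inside the extent."""


class OutOfBoundsError(InvalidInputError):
    """A coordinate falls outside the covariate grid extent."""


class ShapeError(InvalidInputError):
    """Dimension mismatch between coefficients, designs, or maps."""


class SchemaError(InvalidInputError):
    """Column layouts or individual sets disagree between inputs."""


class EmptyDataError(InsufficientDataError):
    """No usable choice sets remain after filtering."""
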