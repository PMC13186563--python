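"""Exception hierarchy shared across the package."""

__all__ = [
    "CombiplateError",
    "ValidationError",
    "CapacityError",
    "SimulationError",
    "IncompleteLandscapeError",
]


class CombiplateError(Exception):
    """Base class for all package errors."""


class ValidationError(CombiplateError, ValueError):
    """Invalid domain input: bad code, index, config or table."""


class CapacityError(CombiplateError):
    """A pipetting plan would overfill a well.

    Carries the offending step index and the volume it would have reached,
    so the failure can be reported rather than hidden.
    """

    def __init__(self, message: str, step_index: int | None = None, volume=None):
        super().__init__(message)
        self.step_index = step_index
        self.volume = volume


class SimulationError(CombiplateError):
    """The transfer simulator hit an impossible state (e.g. empty source)."""


class IncompleteLandscapeError(CombiplateError):
    """An operation requiring a combinatorially complete landscape was
    called on one with missing consortia."""

    def __init__(self, message: str, missing: list[str] | None = None):
        super().__init__(message)
        self.missing = missing or []
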