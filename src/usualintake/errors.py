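"""Exception hierarchy.

Every error raised by the estimation pipeline derives from
:class:`UsualIntakeError` so callers can distinguish data/model problems
from programming errors.  Errors that a user can fix by changing their
input carry an actionable ``hint``.
"""

from __future__ import annotations


class UsualIntakeError(Exception):
    """Base class for all package-specific errors."""

    def __init__(self, message: str, hint: str | None = None):
        self.hint = hint
        if hint:
            message = f"{message}\nHint: {hint}"
        super().__init__(message)


class DataError(UsualIntakeError):
    """Malformed or out-of-contract input data."""


class DomainError(UsualIntakeError, ValueError):
    """A numeric argument outside its mathematical domain."""


class NoVarianceError(DataError):
    """Input has no variation where variation is required (e.g. all intakes equal)."""


class NearlyDailyViolationError(DataError):
    """Too many zero-intake person-days for a nearly-daily dietary component.

    The amount-only model assumes the component is consumed by nearly
    everyone nearly every day; episodically consumed components need a
    two-part (probability x amount) model that this package does not fit.
    """


class GuidanceError(UsualIntakeError):
    """The requested analysis cannot run as specified, but an alternative exists."""


class RankError(DataError):
    """Singular covariate design matrix."""

    def __init__(self, message: str, collinear: list[str] | None = None, hint: str | None = None):
        self.collinear = collinear or []
        super().__init__(message, hint=hint)


class NotConvergedError(UsualIntakeError):
    """A model fit did not converge and the caller refused the fallback."""


class ReplicationError(UsualIntakeError):
    """Invalid replication design or too many replicate failures."""


class ReferenceLookupError(DataError):
    """A person could not be matched to a reference (EAR/UL or requirement) row."""
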