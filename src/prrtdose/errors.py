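"""Exception hierarchy for the dosimetry pipeline.

Every failure a caller may want to branch on gets its own type; all inherit
from :class:`DosimetryError` so library users can catch one base class.
"""

from __future__ import annotations


class DosimetryError(Exception):
    """Base class for all prrtdose errors."""


class TableParseError(DosimetryError):
    """A delimited-text or JSON input could not be parsed or failed schema checks.

    Carries the offending file and, where known, the row label.
    """

    def __init__(self, message: str, *, path: str | None = None, row: object = None):
        detail = message
        if path is not None:
            detail += f" [file: {path}]"
        if row is not None:
            detail += f" [row: {row}]"
        super().__init__(detail)
        self.path = path
        self.row = row


class DataValidationError(DosimetryError):
    """A domain object violates one of its invariants (non-positive volume, etc.)."""


class NonDecayingKineticsError(DosimetryError):
    """A mono-exponential fit produced a non-positive effective decay constant.

    The rejected fit is attached as ``.fit`` so callers can inspect it.
    """

    def __init__(self, message: str, fit=None):
        super().__init__(message)
        self.fit = fit


class MissingDoseFactorError(DosimetryError, KeyError):
    """A (source, target) dose-factor lookup has no entry in the table."""


class MissingRegionError(DosimetryError):
    """A required region has no usable data (e.g. no cycle-1 decay constant)."""


class SingularDesignError(DosimetryError):
    """Regression design matrix is rank-deficient or otherwise degenerate."""


class UnitContractError(DosimetryError):
    """Inputs do not satisfy the unit contract of a coefficient set."""
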