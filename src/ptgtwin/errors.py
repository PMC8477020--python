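"""Exception hierarchy for the ptgtwin pipeline.

All package-specific failures derive from :class:`PTGError` so callers can
catch pipeline errors without swallowing programming errors.
"""


class PTGError(Exception):
    """Base class for all ptgtwin errors."""


class DomainError(PTGError, ValueError):
    """An input value lies outside its physiological/mathematical domain."""


class UnitTagError(PTGError, ValueError):
    """A time stamp carried the wrong unit tag for the requested operation."""


class DegenerateStateError(PTGError):
    """The gland state is degenerate (e.g. total cell mass is zero)."""


class IntegrationError(PTGError, RuntimeError):
    """The ODE solver failed; carries the solver diagnostic message."""


class InsufficientDataError(PTGError):
    """Too few observations to perform the requested operation."""


class NotIndividualizableError(PTGError):
    """The patient cannot be individualized (calcimimetic exposure)."""


class NonConvergenceError(PTGError):
    """No optimizer start converged."""


class UndefinedStatisticError(PTGError):
    """A statistic is undefined for the given input (e.g. zero variance)."""


class ConfigError(PTGError, ValueError):
    """Invalid or unknown configuration content."""


class BundleValidationError(PTGError, ValueError):
    """A tabular input file failed schema validation.

    Parameters
    ----------
    message : str
        Human-readable description.
    rows : sequence of int, optional
        Offending 0-based data-row numbers (excluding the header).
    """

    def __init__(self, message, rows=None):
        self.rows = list(rows) if rows is not None else []
        if self.rows:
            message = f"{message} (rows: {self.rows})"
        super().__init__(message)
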