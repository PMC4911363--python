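"""Exception hierarchy for the leafwue package."""


class LeafWueError(Exception):
    """Base class for all leafwue errors."""


class ParameterError(LeafWueError, ValueError):
    """A model parameter is outside its admissible range."""


class FormatError(LeafWueError, ValueError):
    """An input file is malformed (missing column, bad row, duplicate time)."""


class DomainError(LeafWueError, ValueError):
    """An input lies outside the validity domain of an empirical relation."""


class StateError(LeafWueError, ValueError):
    """A dynamic state variable is physically inadmissible."""


class RangeError(LeafWueError, ValueError):
    """A query time lies outside the span of a forcing series."""


class SolverError(LeafWueError, RuntimeError):
    """No admissible root of the steady-state system could be identified.

    Carries all candidate roots in ``roots`` for diagnosis.
    """

    def __init__(self, message: str, roots=None):
        super().__init__(message)
        self.roots = list(roots) if roots is not None else []


class FittingError(LeafWueError, RuntimeError):
    """Nonlinear parameter estimation failed or the data are unidentifiable."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class UndefinedWUEError(LeafWueError, ZeroDivisionError):
    """Water use efficiency is undefined because the transpiration integral is zero."""
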