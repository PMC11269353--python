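"""Exception hierarchy for ligbind.

Every error raised by the library derives from :class:`LigbindError` so callers
can catch the package's failures with a single except clause. The CLI maps each
subclass to a machine-readable error category and a nonzero exit code.
"""


class LigbindError(Exception):
    """Base class for all ligbind errors."""

    category = "error"


class InvalidInputError(LigbindError, ValueError):
    """Input violates a documented precondition (bad concentrations, empty schedule, ...)."""

    category = "invalid-input"


class SignalOverlapError(LigbindError):
    """A resonance is unusable because it overlaps another signal; the entry is undetermined."""

    category = "signal-overlap"


class NoBindingDetectedError(LigbindError):
    """All amplification factors sit below the detection floor; no build-up to fit."""

    category = "no-binding-detected"


class FitConvergenceError(LigbindError):
    """Nonlinear fit failed to converge and no honest parameter estimate exists."""

    category = "fit-non-convergence"


class EmptyEpitopeMapError(LigbindError):
    """No converged fit with positive initial slope; an epitope map cannot be normalized."""

    category = "empty-epitope-map"


class InsufficientDataError(LigbindError):
    """A probe (or condition) has zero determined entries; names the offending probe."""

    category = "insufficient-data"


class SolverError(LigbindError):
    """Equilibrium solver failed to converge; no partial output is returned."""

    category = "solver-failure"


class SchemaError(LigbindError):
    """A delimited-text table does not conform to its schema; lists offending lines."""

    category = "schema-error"
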