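"""Exception hierarchy shared across the package.

Validation problems (bad concentrations, malformed tables, mismatched
atom sets) raise :class:`ValidationError`; optimizer failures raise
:class:`ConvergenceError`.  The CLI maps these onto exit codes 2 and 3.
"""


class FPBindError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(FPBindError, ValueError):
    """Invalid input values, domains, or shapes."""


class SchemaError(ValidationError):
    """A tabular input does not match the documented schema."""

    def __init__(self, message, missing_columns=()):
        super().__init__(message)
        self.missing_columns = tuple(missing_columns)


class ConvergenceError(FPBindError, RuntimeError):
    """A root finder or least-squares fit failed to converge."""


class DegenerateModelError(FPBindError, ValueError):
    """A model cannot be fitted because the data carry no variance."""
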