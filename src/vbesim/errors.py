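"""Exception hierarchy.

Exit-code mapping used by the CLI: ConfigError -> 2, DataError -> 3,
NumericalError -> 4.
"""


class VbesimError(Exception):
    """Base class for all package errors."""


class ConfigError(VbesimError):
    """Invalid or inconsistent configuration (unknown preset, bad parameter name...)."""


class DataError(VbesimError):
    """Invalid input data."""


class GridMismatchError(DataError):
    """Two profiles do not share the same time grid."""


class InsufficientDataError(DataError):
    """Too few data points for the requested operation."""


class UnderdeterminedError(DataError):
    """Fewer observations than free parameters."""


class NumericalError(VbesimError):
    """Numerical failure (non-convergence, integration error...)."""


class ConvergenceError(NumericalError):
    """Optimizer failed to converge; carries diagnostics."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class IntegrationError(NumericalError):
    """ODE solver failure."""
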