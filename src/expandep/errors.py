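"""Exception hierarchy shared across the package.

The CLI maps these onto process exit codes: configuration problems exit
with 2, numeric non-convergence with 3 and I/O failures with 4.
"""


class ExpandepError(Exception):
    """Base class for all package-specific errors."""


class DomainError(ExpandepError, ValueError):
    """An argument is outside its physically meaningful range."""


class ConfigurationError(ExpandepError):
    """Inconsistent or unresolvable configuration (exit code 2)."""


class UnsupportedConfigurationError(ConfigurationError):
    """The requested quantity is undefined for this electrode variant."""


class GeometryError(ExpandepError):
    """Needle geometry does not fit the simulation grid."""


class SolverConvergenceError(ExpandepError):
    """Linear or fixed-point iteration failed to converge (exit code 3)."""

    def __init__(self, message: str, residual: float | None = None):
        super().__init__(message)
        self.residual = residual


class MaskIOError(ExpandepError):
    """A segmentation mask could not be read or written (exit code 4)."""
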