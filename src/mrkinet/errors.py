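"""Exception hierarchy used across the package.

All user-facing failures derive from :class:`MrkinetError` so callers can
catch one base class; validation problems (bad shapes, units, domains) and
format problems (malformed CSV/JSON) are distinguished from numerical
failures of the integrator or optimizer.
"""


class MrkinetError(Exception):
    """Base class for all package errors."""


class ValidationError(MrkinetError, ValueError):
    """Input violates a documented invariant (shape, sign, units, domain)."""


class FormatError(ValidationError):
    """A file could not be parsed into the expected structure."""


class IntegrationError(MrkinetError, RuntimeError):
    """The ODE solver failed; carries the time at which it gave up."""

    def __init__(self, message: str, t_fail: float | None = None):
        super().__init__(message)
        self.t_fail = t_fail


class EstimationError(MrkinetError, RuntimeError):
    """No optimization start converged; carries per-start diagnostics."""

    def __init__(self, message: str, diagnostics: list | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or []
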