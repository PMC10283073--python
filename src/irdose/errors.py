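"""Exception hierarchy for the irdose package."""


class IrdoseError(Exception):
    """Base class for all package errors."""


class TrialParseError(IrdoseError):
    """A trials CSV row could not be parsed; carries the offending row number."""

    def __init__(self, row: int, message: str):
        self.row = row
        super().__init__(f"row {row}: {message}")


class ValidationError(IrdoseError):
    """A value violates a domain invariant (e.g. unknown outcome category)."""


class DegenerateVarianceError(IrdoseError):
    """Cell sizes cannot be normalized (fewer than two, or all identical)."""


class CoverageError(IrdoseError):
    """A record's laser power falls outside every frequency bin."""


class DegenerateOutcomeError(IrdoseError):
    """An endpoint is constant (all 0 or all 1); a logistic fit is undefined."""


class DomainError(IrdoseError):
    """A parameter combination leaves the model's valid domain."""


class UsageError(IrdoseError):
    """An operation was called with structurally incompatible arguments."""


class McmcConvergenceError(IrdoseError):
    """MCMC diagnostics exceeded the configured thresholds.

    Carries per-parameter diagnostics in ``diagnostics``.
    """

    def __init__(self, message: str, diagnostics: dict | None = None):
        self.diagnostics = diagnostics or {}
        super().__init__(message)
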