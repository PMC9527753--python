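"""Exception hierarchy for kinsense.

All domain errors derive from :class:`KinsenseError` so callers can catch
one base class at pipeline boundaries (the CLI maps them to exit code 2,
and non-convergence to exit code 3).
"""


class KinsenseError(Exception):
    """Base class for all kinsense domain errors."""


class InvalidParameterError(KinsenseError, ValueError):
    """A kinetic parameter violates its physical constraints."""


class OutOfWindowError(KinsenseError, ValueError):
    """A time point lies outside the phase window of the requested model."""


class InvalidDesignError(KinsenseError, ValueError):
    """A series design or noise specification is unusable."""


class GuessFailureError(KinsenseError, RuntimeError):
    """Initial-guess heuristics could not extract usable starting values.

    Carries a ``diagnostics`` dict describing which trace and which step
    failed.
    """

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class IdentifiabilityError(KinsenseError, ValueError):
    """The data cannot separate the requested parameters (e.g. a single
    concentration cannot split k_obs into k_a and k_d)."""


class ConvergenceError(KinsenseError, RuntimeError):
    """The optimizer failed to converge and the caller required convergence."""


class AggregationMismatchError(KinsenseError, ValueError):
    """Replicate results describe different systems/temperatures/modes."""


class ValidationError(KinsenseError, ValueError):
    """Manifest or file validation failed; ``failures`` lists every problem."""

    def __init__(self, failures: list[str]):
        self.failures = list(failures)
        super().__init__("; ".join(self.failures))
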