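"""Exception hierarchy for the nasalair package."""


class NasalAirError(Exception):
    """Base class for all package errors."""


class ValidationError(NasalAirError, ValueError):
    """Input violates a documented precondition or invariant."""


class ParseError(NasalAirError, ValueError):
    """A profile or probe CSV could not be parsed into typed data."""


class DegenerateScenarioError(ValidationError):
    """Wall and external reference values coincide; theta is undefined."""


class FitConvergenceError(NasalAirError, RuntimeError):
    """The hyperbola optimizer hit a bound or failed to converge.

    Carries the best fit found so far in ``best``.
    """

    def __init__(self, message, best=None):
        super().__init__(message)
        self.best = best


class ConfigError(NasalAirError, ValueError):
    """Pipeline configuration is invalid; lists the offending keys."""
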