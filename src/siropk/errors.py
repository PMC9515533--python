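"""Exception hierarchy for siropk."""


class SiropkError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(SiropkError, ValueError):
    """A structural or population parameter violates its domain."""


class DegenerateKineticsError(SiropkError, ValueError):
    """Absorption and elimination rate constants coincide (flip-flop limit)."""


class InvalidCovariateError(SiropkError, ValueError):
    """A covariate value is outside its admissible domain (e.g. WT <= 0)."""


class ConfigError(SiropkError, ValueError):
    """Malformed model or scenario configuration."""


class SchemaError(SiropkError, ValueError):
    """Dataset file violates the documented CSV schema."""


class EstimationError(SiropkError, RuntimeError):
    """Likelihood evaluation or optimization failed irrecoverably."""


class DiagnosticError(SiropkError, RuntimeError):
    """A goodness-of-fit quantity could not be computed."""


class NoFeasibleDoseError(SiropkError, RuntimeError):
    """No dose on the candidate grid attains the target window."""
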