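"""Exception types shared across the package."""


class ConfigurationError(ValueError):
    """A configuration value, unit tag or schema field is invalid."""


class InvalidMeasurementError(ValueError):
    """A rate measurement violates its invariants (e.g. negative rate)."""


class InsufficientDataError(ValueError):
    """Too few distinct data points to identify the model."""


class NotConvergedError(RuntimeError):
    """A computation that requires a converged steady state received one
    that did not converge."""
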