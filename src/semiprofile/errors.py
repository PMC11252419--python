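"""Exception types shared across the package."""


class ConfigurationError(ValueError):
    """Invalid configuration (dimensions, thresholds, schedules)."""


class DataError(ValueError):
    """Invalid or degenerate input data."""


class TrainingDivergedError(RuntimeError):
    """Raised when a training stage produces a non-finite loss."""
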