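"""Exception types shared across the package."""


class ConfigError(ValueError):
    """An invalid configuration value (e.g. allele-frequency range outside (0, 0.5])."""


class ZeroVarianceError(ValueError):
    """A quantity that must have positive variance is constant."""


class ShapeError(ValueError):
    """Array dimensions incompatible with the requested operation."""


class UndefinedCorrelationError(ValueError):
    """Pearson correlation is undefined (zero variance or too few points)."""


class TrainingDivergedError(RuntimeError):
    """Non-finite loss encountered during optimisation."""
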