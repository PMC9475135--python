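"""Exception hierarchy for stressorpower."""


class StressorPowerError(ValueError):
    """Base class for all validation and domain errors raised by this package."""


class DegenerateExperimentError(StressorPowerError):
    """Raised when a factorial experiment has too few replicates (ΣNx − 4 < 1)."""


class ZeroPooledSDError(StressorPowerError):
    """Raised when the pooled standard deviation is zero, so a standardized
    effect size is undefined."""


class NonPositiveMeanError(StressorPowerError):
    """Raised by the multiplicative (log response ratio) model when a treatment
    mean is not strictly positive; the additive model should be used instead."""


class ModelMismatchError(StressorPowerError):
    """Raised when an effect-size result is combined with experiment data it
    could not have been computed from (e.g. a multiplicative result with
    non-positive means)."""


class InfeasibleConfigurationError(StressorPowerError):
    """Raised when no critical effect size exists for a sample-size/alpha
    configuration (the defining equation has no positive root)."""


class NoDetectionsError(StressorPowerError):
    """Raised when a detection-bias ratio is requested but no simulation
    rejected the null model."""


class InfeasibleMixError(StressorPowerError):
    """Raised when a fixture label mix cannot be satisfied by the configured
    mean/effect ranges."""
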