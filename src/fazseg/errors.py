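"""Exception hierarchy for the FAZ segmentation pipeline."""


class FazSegError(Exception):
    """Base class for all pipeline errors."""


class DegenerateInputError(FazSegError):
    """Raised for inputs with no usable signal (e.g. zero dynamic range)."""


class ParameterError(FazSegError, ValueError):
    """Raised when a configuration value violates its documented bounds."""


class NoFazFoundError(FazSegError):
    """Raised when no candidate survives filtering: a localization failure.

    Callers running batch evaluations should catch this and record the
    image as a localization failure rather than aborting.
    """


class UndefinedMetricError(FazSegError):
    """Raised when a metric is mathematically undefined for its inputs
    (e.g. Jaccard of two empty masks, Pearson r with zero variance)."""
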