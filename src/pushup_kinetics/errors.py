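"""Exception hierarchy for the push-up kinetics pipeline.

Every error raised by the pipeline derives from :class:`PushUpError`.  When an
error propagates out of :func:`pushup_kinetics.kinetics.analyze_trial` the
pipeline stage that raised it is attached as the ``stage`` attribute.
"""


class PushUpError(Exception):
    """Base class for all pipeline errors."""

    #: name of the pipeline stage that raised the error (set by analyze_trial)
    stage: str | None = None


class FormatError(PushUpError):
    """Input file does not match the expected delimited-text schema."""


class SamplingError(PushUpError):
    """Time column is non-uniform beyond tolerance or otherwise unusable."""


class EmptyInputError(PushUpError):
    """Input contains too few rows/samples to analyze."""


class ConfigurationError(PushUpError):
    """Invalid analysis configuration (e.g. cutoff at or above Nyquist)."""


class UnstableBaselineError(PushUpError):
    """The static window is not quiescent enough to define a baseline."""


class MissingMassError(PushUpError):
    """One-platform acquisition without a supplied body mass."""


class NoMovementError(PushUpError):
    """Hands force never drops below the start threshold."""


class NoTakeoffError(PushUpError):
    """Hands force never drops below the takeoff threshold after the start."""


class PhaseOrderError(PushUpError):
    """Threshold crossings occur in an impossible order, or the detected
    phase is too short to be a real push-up."""


class MethodUnavailableError(PushUpError):
    """Requested calculation method cannot run on this recording."""


class SimulationInfeasibleError(PushUpError):
    """Simulator parameters cannot produce a hands takeoff."""


class StatisticsError(PushUpError):
    """Invalid input to a statistical routine."""


class UndefinedEffectSizeError(StatisticsError):
    """Cohen's d is undefined (both group SDs are zero)."""


class UndefinedCorrelationError(StatisticsError):
    """Correlation is undefined (a constant input vector)."""
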