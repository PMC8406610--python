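"""Filtering and static-baseline estimation.

Raw platform signals are low-pass filtered (4th-order Butterworth, 100 Hz
cutoff by default) with a forward–backward pass so the filter is zero-phase:
detected events are not shifted in time.  The static baseline — body weight
and the initial hands/feet force split — is the mean of the filtered traces
over the quiescent window at the start of the recording (first 0.5 s by
default), during which the participant holds the starting position.

In a two-platform acquisition body weight is the sum of the two static means
and body mass is derived from it; in a one-platform acquisition body mass
must be supplied and the static feet force is body weight minus the static
hands force.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, filtfilt

from .errors import (
    ConfigurationError,
    EmptyInputError,
    MissingMassError,
    UnstableBaselineError,
)
from .signal_io import AnalysisConfig, ForceTrace, PushUpRecording

__all__ = ["Baseline", "lowpass_filter", "filter_recording", "compute_baseline"]


@dataclass(frozen=True)
class Baseline:
    """Static reference values for one recording.

    All forces in newtons.  ``feet_static`` is measured (two-platform) or
    derived as ``body_weight - hands_static`` (one-platform).
    """

    body_weight: float
    hands_static: float
    feet_static: float
    body_mass: float
    window: tuple[float, float]

    @property
    def feet_share(self) -> float:
        """Fraction of body weight carried by the feet at the start."""
        return self.feet_static / self.body_weight

    @property
    def hands_share(self) -> float:
        """Fraction of body weight carried by the hands at the start."""
        return self.hands_static / self.body_weight


def lowpass_filter(trace: ForceTrace, config: AnalysisConfig | None = None) -> ForceTrace:
    """Zero-phase low-pass Butterworth filter of one trace.

    The filter is applied forward and backward (``scipy.signal.filtfilt``)
    with reflective ("even") padding, so the response has no phase shift and
    unit DC gain.  The nominal cutoff is used per pass; no double-pass cutoff
    correction is applied.
    """
    config = config or AnalysisConfig()
    nyquist = trace.sampling_rate / 2.0
    if config.filter_cutoff_hz >= nyquist:
        raise ConfigurationError(
            f"cutoff {config.filter_cutoff_hz} Hz is not below Nyquist {nyquist} Hz"
        )
    # filtfilt needs padlen < n; require a comfortable margin over the order
    padlen = 3 * (config.filter_order + 1)
    if len(trace) <= max(padlen, 3 * config.filter_order):
        raise EmptyInputError(
            f"trace of {len(trace)} samples is too short for an order-"
            f"{config.filter_order} zero-phase filter"
        )
    b, a = butter(config.filter_order, config.filter_cutoff_hz, fs=trace.sampling_rate)
    filtered = filtfilt(b, a, trace.samples, padtype="even", padlen=padlen)
    return trace.with_samples(filtered)


def filter_recording(
    recording: PushUpRecording, config: AnalysisConfig | None = None
) -> PushUpRecording:
    """Apply :func:`lowpass_filter` to every present trace."""
    config = config or AnalysisConfig()
    return recording.map_traces(lambda trace: lowpass_filter(trace, config))


def compute_baseline(
    recording: PushUpRecording, config: AnalysisConfig | None = None
) -> Baseline:
    """Estimate the static baseline from the start of a filtered recording.

    The first ``baseline_window_s`` seconds must be quiescent: the standard
    deviation of each present (filtered) trace over the window must stay
    below ``quiescence_sd_N``.

    Raises
    ------
    UnstableBaselineError
        If the window is not quiescent.
    MissingMassError
        One-platform recording without a supplied ``body_mass``.
    """
    config = config or AnalysisConfig()
    n_window = int(round(config.baseline_window_s * recording.sampling_rate))
    if n_window < 2:
        raise ConfigurationError("baseline window shorter than 2 samples")
    if n_window > len(recording.hands):
        raise EmptyInputError("recording shorter than the baseline window")
    window = (0.0, n_window / recording.sampling_rate)

    def window_stats(trace: ForceTrace) -> tuple[float, float]:
        segment = trace.samples[:n_window]
        return float(np.mean(segment)), float(np.std(segment))

    hands_static, hands_sd = window_stats(recording.hands)
    if hands_sd >= config.quiescence_sd_N:
        raise UnstableBaselineError(
            f"hands force SD {hands_sd:.2f} N over the baseline window exceeds "
            f"{config.quiescence_sd_N:.2f} N"
        )

    if recording.feet is not None:
        feet_static, feet_sd = window_stats(recording.feet)
        if feet_sd >= config.quiescence_sd_N:
            raise UnstableBaselineError(
                f"feet force SD {feet_sd:.2f} N over the baseline window exceeds "
                f"{config.quiescence_sd_N:.2f} N"
            )
        body_weight = hands_static + feet_static
        body_mass = body_weight / config.gravity
    else:
        if recording.body_mass is None:
            raise MissingMassError(
                "one-platform recording requires a supplied body mass"
            )
        body_mass = recording.body_mass
        body_weight = body_mass * config.gravity
        feet_static = body_weight - hands_static

    if body_weight <= 0:
        raise UnstableBaselineError("non-positive body weight from baseline window")
    return Baseline(
        body_weight=body_weight,
        hands_static=hands_static,
        feet_static=feet_static,
        body_mass=body_mass,
        window=window,
    )
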