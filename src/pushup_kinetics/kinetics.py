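"""Whole-body force, velocity and power over the push-up phase.

Two calculation methods are implemented:

* **two_platform** — whole-body force is the measured sum
  ``F_hands(t) + F_feet(t)``;
* **one_platform** — the feet force is assumed constant at its static value
  (body weight minus the static hands force), so whole-body force is
  ``F_hands(t) + feet_static``.

Whole-body (center-of-mass) velocity follows from the impulse–momentum
theorem: the cumulative trapezoidal integral of the net force
``F_total - m g`` divided by body mass, with ``v = 0`` at the phase start
(the participant holds a static position before descending).  Power is the
sample-wise product of whole-body force and velocity.

Eight outcome variables are extracted per method; forces and power are
normalized to body weight (forces in BW units, power in W per N of body
weight — numerically m/s).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .errors import (
    EmptyInputError,
    FormatError,
    MethodUnavailableError,
    PushUpError,
)
from .phase_detection import PushUpPhase, detect_phase
from .preprocessing import Baseline, compute_baseline, filter_recording
from .signal_io import AnalysisConfig, PushUpRecording

__all__ = [
    "EightVariables",
    "MethodResult",
    "TrialAnalysis",
    "total_force_two_platform",
    "total_force_one_platform",
    "impulse_velocity",
    "power_series",
    "extract_variables",
    "analyze_trial",
]


@dataclass(frozen=True)
class EightVariables:
    """The eight outcome variables of one method on one trial.

    Forces are in body-weight (BW) units, power in W per N of body weight,
    velocities in m/s (upward positive).
    """

    peak_hands_grf_BW: float
    peak_wholebody_grf_BW: float
    peak_wholebody_velocity_mps: float
    peak_wholebody_power_WperBW: float
    feet_grf_start_BW: float
    mean_feet_grf_BW: float
    wholebody_grf_at_peak_power_BW: float
    wholebody_velocity_at_peak_power_mps: float

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in self.__dataclass_fields__}


@dataclass(frozen=True)
class MethodResult:
    """Per-method series over the push-up phase plus extracted variables."""

    method: str  # "two_platform" | "one_platform"
    time_s: np.ndarray
    total_force: np.ndarray  # newtons
    velocity: np.ndarray  # m/s, upward positive
    power: np.ndarray  # watts
    variables: EightVariables
    body_weight: float  # newtons, for normalization

    @property
    def total_force_BW(self) -> np.ndarray:
        return self.total_force / self.body_weight

    @property
    def power_BW(self) -> np.ndarray:
        return self.power / self.body_weight


@dataclass(frozen=True)
class TrialAnalysis:
    """Full analysis of one trial: shared phase/baseline, per-method results.

    ``two_platform`` is ``None`` for one-platform acquisitions.
    """

    recording: PushUpRecording  # filtered traces
    baseline: Baseline
    phase: PushUpPhase
    one_platform: MethodResult
    two_platform: MethodResult | None = None

    def results(self) -> Iterator[MethodResult]:
        """Available method results, two-platform first."""
        if self.two_platform is not None:
            yield self.two_platform
        yield self.one_platform

    @property
    def methods(self) -> tuple[str, ...]:
        return tuple(result.method for result in self.results())


def _phase_slice(phase: PushUpPhase, n: int) -> slice:
    if phase.end_index > n:
        raise FormatError("phase extends beyond the trace")
    if phase.n_samples < 2:
        raise EmptyInputError("phase shorter than 2 samples")
    return phase.slice


def total_force_two_platform(
    recording: PushUpRecording, phase: PushUpPhase
) -> np.ndarray:
    """Measured whole-body force: hands + feet, over the phase."""
    if recording.feet is None:
        raise MethodUnavailableError("two-platform method needs a feet trace")
    sl = _phase_slice(phase, len(recording.hands))
    return recording.hands.samples[sl] + recording.feet.samples[sl]


def total_force_one_platform(
    recording: PushUpRecording, phase: PushUpPhase, baseline: Baseline
) -> np.ndarray:
    """Whole-body force under the constant-feet-force assumption."""
    sl = _phase_slice(phase, len(recording.hands))
    return recording.hands.samples[sl] + baseline.feet_static


def impulse_velocity(
    total_force: np.ndarray,
    body_mass: float,
    sampling_rate: float,
    gravity: float = 9.81,
) -> np.ndarray:
    """Center-of-mass velocity from the impulse–momentum theorem.

    ``v[k]`` is the cumulative trapezoidal integral of
    ``(F_total - m g) / m`` from the phase start to sample ``k``;
    ``v[0] = 0``.
    """
    total_force = np.asarray(total_force, dtype=float)
    if total_force.size < 2:
        raise EmptyInputError("need at least 2 force samples to integrate")
    if not np.all(np.isfinite(total_force)):
        raise FormatError("non-finite values in the force series")
    if not body_mass > 0:
        raise FormatError("body_mass must be positive")
    net_accel = total_force / body_mass - gravity
    return cumulative_trapezoid(net_accel, dx=1.0 / sampling_rate, initial=0.0)


def power_series(total_force: np.ndarray, velocity: np.ndarray) -> np.ndarray:
    """Whole-body power: sample-wise product of force and velocity."""
    total_force = np.asarray(total_force, dtype=float)
    velocity = np.asarray(velocity, dtype=float)
    if total_force.shape != velocity.shape:
        raise FormatError(
            f"force and velocity lengths differ: {total_force.shape} vs "
            f"{velocity.shape}"
        )
    return total_force * velocity


def extract_variables(
    recording: PushUpRecording,
    phase: PushUpPhase,
    baseline: Baseline,
    method: str,
    total_force: np.ndarray,
    velocity: np.ndarray,
    power: np.ndarray,
) -> EightVariables:
    """Extract the eight outcome variables for one method.

    Peaks are maxima of the signed series over the phase (first occurrence on
    ties; ``np.argmax`` returns the first maximum).  The force and velocity
    "at peak power" are read at the sample index of the power maximum.  The
    mean feet force uses the measured (filtered) feet trace for the
    two-platform method and is the static constant by construction for the
    one-platform method.
    """
    if total_force.size == 0:
        raise EmptyInputError("empty phase")
    sl = _phase_slice(phase, len(recording.hands))
    bw = baseline.body_weight

    if method == "two_platform":
        if recording.feet is None:
            raise MethodUnavailableError("two-platform method needs a feet trace")
        mean_feet = float(np.mean(recording.feet.samples[sl]))
    elif method == "one_platform":
        mean_feet = baseline.feet_static
    else:
        raise FormatError(f"unknown method {method!r}")

    peak_power_idx = int(np.argmax(power))
    return EightVariables(
        peak_hands_grf_BW=float(np.max(recording.hands.samples[sl])) / bw,
        peak_wholebody_grf_BW=float(np.max(total_force)) / bw,
        peak_wholebody_velocity_mps=float(np.max(velocity)),
        peak_wholebody_power_WperBW=float(np.max(power)) / bw,
        feet_grf_start_BW=baseline.feet_static / bw,
        mean_feet_grf_BW=mean_feet / bw,
        wholebody_grf_at_peak_power_BW=float(total_force[peak_power_idx]) / bw,
        wholebody_velocity_at_peak_power_mps=float(velocity[peak_power_idx]),
    )


def _method_result(
    recording: PushUpRecording,
    phase: PushUpPhase,
    baseline: Baseline,
    method: str,
    total_force: np.ndarray,
    config: AnalysisConfig,
) -> MethodResult:
    velocity = impulse_velocity(
        total_force, baseline.body_mass, recording.sampling_rate, config.gravity
    )
    power = power_series(total_force, velocity)
    variables = extract_variables(
        recording, phase, baseline, method, total_force, velocity, power
    )
    time_s = (
        np.arange(phase.start_index, phase.end_index) / recording.sampling_rate
    )
    return MethodResult(
        method=method,
        time_s=time_s,
        total_force=total_force,
        velocity=velocity,
        power=power,
        variables=variables,
        body_weight=baseline.body_weight,
    )


def _stage(name: str):
    """Context manager attaching the stage name to propagating errors."""

    class _Stage:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and isinstance(exc, PushUpError):
                exc.stage = name
            return False

    return _Stage()


def analyze_trial(
    recording: PushUpRecording, config: AnalysisConfig | None = None
) -> TrialAnalysis:
    """Run the full pipeline on one raw recording.

    Stages: low-pass filter both traces → static baseline → phase detection
    on the filtered hands trace → whole-body force / velocity / power under
    each available method → variable extraction.  Both method results share
    the same phase and baseline.  Errors raised by a stage propagate with the
    stage name attached as their ``stage`` attribute.
    """
    config = config or AnalysisConfig()
    with _stage("filter"):
        filtered = filter_recording(recording, config)
    with _stage("baseline"):
        baseline = compute_baseline(filtered, config)
    with _stage("phase_detection"):
        phase = detect_phase(filtered.hands, baseline, config)
    with _stage("kinetics"):
        one_force = total_force_one_platform(filtered, phase, baseline)
        one_result = _method_result(
            filtered, phase, baseline, "one_platform", one_force, config
        )
        two_result = None
        if filtered.feet is not None:
            two_force = total_force_two_platform(filtered, phase)
            two_result = _method_result(
                filtered, phase, baseline, "two_platform", two_force, config
            )
    return TrialAnalysis(
        recording=filtered,
        baseline=baseline,
        phase=phase,
        one_platform=one_result,
        two_platform=two_result,
    )
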