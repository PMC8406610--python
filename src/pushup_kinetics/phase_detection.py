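"""Push-up phase detection on the hands force trace.

The push-up phase is bounded by two first-crossing events on the filtered
hands force:

* **start** — the first sample where the hands force drops more than 15 N
  below its static baseline value (movement onset as the body begins to
  accelerate downward);
* **end** — the first sample after the start where the hands force drops
  below 15 N (hand takeoff).

Comparisons are strict (``<``), at sample resolution, with no interpolation
or debouncing: at 1000 Hz the quantization is at most 1 ms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import NoMovementError, NoTakeoffError, PhaseOrderError
from .preprocessing import Baseline
from .signal_io import AnalysisConfig, ForceTrace

__all__ = ["PushUpPhase", "detect_phase"]

#: shortest phase accepted as a real push-up, seconds
MIN_PHASE_DURATION_S = 0.1


@dataclass(frozen=True)
class PushUpPhase:
    """Detected push-up phase: ``[start_index, end_index)`` sample slice.

    ``end_index`` is exclusive; the last sample inside the phase
    (``end_index - 1``) is the first sample below the takeoff threshold, and
    is included in all integrals over the phase.
    """

    start_index: int
    end_index: int
    start_time_s: float
    end_time_s: float
    baseline: Baseline

    def __post_init__(self) -> None:
        if not 0 <= self.start_index < self.end_index:
            raise PhaseOrderError(
                f"invalid phase indices [{self.start_index}, {self.end_index})"
            )

    @property
    def n_samples(self) -> int:
        return self.end_index - self.start_index

    @property
    def duration_s(self) -> float:
        return self.end_time_s - self.start_time_s

    @property
    def slice(self) -> slice:
        return slice(self.start_index, self.end_index)


def detect_phase(
    hands: ForceTrace,
    baseline: Baseline,
    config: AnalysisConfig | None = None,
) -> PushUpPhase:
    """Locate the push-up phase on a filtered hands trace.

    Raises
    ------
    NoMovementError
        Hands force never drops below ``hands_static - threshold``.
    NoTakeoffError
        No sample after the start drops below ``threshold``.
    PhaseOrderError
        The force is below the takeoff threshold before movement onset, or
        the detected phase is implausibly short (< 0.1 s).
    """
    config = config or AnalysisConfig()
    threshold = config.phase_threshold_N
    force = hands.samples

    start_candidates = np.flatnonzero(force < baseline.hands_static - threshold)
    if start_candidates.size == 0:
        raise NoMovementError(
            f"hands force never drops below static - {threshold:g} N"
        )
    start = int(start_candidates[0])

    below_takeoff = np.flatnonzero(force < threshold)
    if below_takeoff.size and below_takeoff[0] < start:
        raise PhaseOrderError(
            f"hands force below {threshold:g} N at sample {below_takeoff[0]}, "
            f"before movement onset at sample {start}"
        )
    end_candidates = below_takeoff[below_takeoff > start]
    if end_candidates.size == 0:
        raise NoTakeoffError(f"hands force never drops below {threshold:g} N")
    takeoff = int(end_candidates[0])

    phase = PushUpPhase(
        start_index=start,
        end_index=takeoff + 1,
        start_time_s=start / hands.sampling_rate,
        end_time_s=takeoff / hands.sampling_rate,
        baseline=baseline,
    )
    if phase.duration_s <= MIN_PHASE_DURATION_S:
        raise PhaseOrderError(
            f"detected phase of {phase.duration_s * 1000:.0f} ms is too short "
            "to be a push-up"
        )
    return phase
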