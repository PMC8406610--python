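import numpy as np
import pytest

from pushup_kinetics import (
    AnalysisConfig,
    ForceTrace,
    PushUpRecording,
    SimParams,
    analyze_trial,
    simulate_trial,
)


@pytest.fixture(scope="session")
def config() -> AnalysisConfig:
    return AnalysisConfig()


@pytest.fixture(scope="session")
def noiseless_trial():
    """Default noiseless synthetic trial: (recording, ground_truth)."""
    return simulate_trial(SimParams(noise_sd_N=0.0))


@pytest.fixture(scope="session")
def noiseless_analysis(noiseless_trial):
    recording, _ = noiseless_trial
    return analyze_trial(recording)


def make_static_recording(
    body_weight: float = 700.0,
    feet_share: float = 0.34,
    n: int = 1000,
    rate: float = 1000.0,
    body_mass: float | None = None,
) -> PushUpRecording:
    """A purely static recording: constant forces at the given split."""
    hands = np.full(n, (1.0 - feet_share) * body_weight)
    feet = np.full(n, feet_share * body_weight)
    return PushUpRecording(
        hands=ForceTrace(hands, rate, "hands"),
        feet=ForceTrace(feet, rate, "feet"),
        body_mass=body_mass,
    )
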