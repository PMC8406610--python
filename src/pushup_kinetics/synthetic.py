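"""Mechanistic synthetic plyometric push-up recordings with analytic ground truth.

The generator builds a piecewise-smooth vertical center-of-mass (COM)
acceleration ``a(t)``: zero during an initial quiet hold, a raised-cosine
negative lobe (countermovement descent), then a raised-cosine positive lobe
(propulsive push).  Whole-body force follows from Newton's second law,
``F_total(t) = m (g + a(t))``, and is split between the platforms by a smooth
feet-share function ``s(t)``:

* ``s = static_feet_share`` (default 0.34) during the quiet hold — the hands
  carry the remaining ~66% of body weight;
* ``s`` dips by ``feet_dip_depth`` during the descent as the COM shifts
  forward over the hands, and stays depressed through most of the push —
  the feet force is below its initial value for most of the movement;
* ``s`` rises toward ``feet_end_share`` (≈1) over the last
  ``share_rise_duration_s`` of the push, driving the hands force through the
  15 N takeoff threshold.

Raised-cosine lobes have closed-form velocity antiderivatives, so the
generator returns exact analytic acceleration/velocity/share functions plus
the outcome variables each calculation method should produce — an oracle for
every pipeline stage.  Force conservation ``F_hands + F_feet = m (g + a)``
holds exactly before noise; optional white Gaussian sensor noise is added
independently per platform.

Default parameters emulate a physically active young adult: the descent and
push lobes (−4.0 m/s² × 0.35 s, +4.4 m/s² × 0.73 s) give a takeoff velocity
near 0.90 m/s and a peak whole-body force near 1.45 BW, and the share dip
(0.11) gives a phase-mean feet force near 0.30 BW from the 0.34 start share.
:func:`simulate_cohort` draws per-participant parameters from truncated
normal distributions with sex-specific means (males push harder and load the
hands more).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np
import yaml
from scipy.integrate import cumulative_trapezoid
from scipy.optimize import brentq
from scipy.stats import truncnorm

from .errors import ConfigurationError, SimulationInfeasibleError
from .kinetics import EightVariables
from .signal_io import ForceTrace, PushUpRecording

__all__ = [
    "SimParams",
    "SimGroundTruth",
    "ParamDist",
    "CohortSpec",
    "simulate_trial",
    "simulate_cohort",
    "make_method_comparison_recording",
    "default_cohort_spec",
]

_TAKEOFF_THRESHOLD_N = 15.0  # hands force defining takeoff in the target pipeline


def _smoothstep(u: np.ndarray | float) -> np.ndarray | float:
    """Cubic smoothstep 3u² − 2u³ clamped to [0, 1]."""
    u = np.clip(u, 0.0, 1.0)
    return u * u * (3.0 - 2.0 * u)


@dataclass(frozen=True)
class SimParams:
    """Parameters of one synthetic trial.

    Accelerations are peak lobe values in m/s² (descent negative, push
    positive); durations in seconds; shares are fractions of whole-body
    force carried by the feet.
    """

    body_mass_kg: float = 70.2
    static_feet_share: float = 0.34
    quiet_duration_s: float = 1.0
    descent_duration_s: float = 0.35
    push_duration_s: float = 0.73
    descent_peak_accel: float = -4.0
    push_peak_accel: float = 4.4
    feet_dip_depth: float = 0.11
    feet_end_share: float = 0.99
    share_rise_duration_s: float = 0.12
    tail_duration_s: float = 0.3
    noise_sd_N: float = 0.0
    gravity: float = 9.81
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.body_mass_kg > 0:
            raise ConfigurationError("body_mass_kg must be > 0")
        if not 0.0 < self.static_feet_share < 1.0:
            raise ConfigurationError("static_feet_share must be in (0, 1)")
        if not 0.0 < self.feet_end_share <= 1.0:
            raise ConfigurationError("feet_end_share must be in (0, 1]")
        if not 0.0 <= self.feet_dip_depth < self.static_feet_share:
            raise ConfigurationError(
                "feet_dip_depth must be in [0, static_feet_share)"
            )
        for name in (
            "quiet_duration_s",
            "descent_duration_s",
            "push_duration_s",
            "tail_duration_s",
        ):
            if not getattr(self, name) > 0:
                raise ConfigurationError(f"{name} must be > 0")
        if not 0.0 < self.share_rise_duration_s <= self.push_duration_s:
            raise ConfigurationError(
                "share_rise_duration_s must be in (0, push_duration_s]"
            )
        if self.descent_peak_accel >= 0:
            raise ConfigurationError("descent_peak_accel must be negative")
        if self.push_peak_accel <= 0:
            raise ConfigurationError("push_peak_accel must be positive")
        if self.noise_sd_N < 0:
            raise ConfigurationError("noise_sd_N must be >= 0")

    # --- movement landmarks -------------------------------------------------
    @property
    def onset_time_s(self) -> float:
        """Configured movement onset (start of the descent lobe)."""
        return self.quiet_duration_s

    @property
    def push_start_s(self) -> float:
        return self.quiet_duration_s + self.descent_duration_s

    @property
    def push_end_s(self) -> float:
        return self.push_start_s + self.push_duration_s

    @property
    def total_duration_s(self) -> float:
        return self.push_end_s + self.tail_duration_s

    @property
    def min_feet_share(self) -> float:
        return self.static_feet_share - self.feet_dip_depth

    # --- analytic model -----------------------------------------------------
    def accel(self, t: np.ndarray | float) -> np.ndarray:
        """COM vertical acceleration a(t), m/s², upward positive."""
        t = np.asarray(t, dtype=float)
        a = np.zeros_like(t)
        t0, t1, t2 = self.onset_time_s, self.push_start_s, self.push_end_s
        descent = (t >= t0) & (t < t1)
        tau = (t[descent] - t0) / self.descent_duration_s
        a[descent] = self.descent_peak_accel * 0.5 * (1.0 - np.cos(2 * np.pi * tau))
        push = (t >= t1) & (t < t2)
        tau = (t[push] - t1) / self.push_duration_s
        a[push] = self.push_peak_accel * 0.5 * (1.0 - np.cos(2 * np.pi * tau))
        return a

    def velocity(self, t: np.ndarray | float) -> np.ndarray:
        """Exact COM velocity: the closed-form antiderivative of accel.

        A raised-cosine lobe of peak A over duration T integrates to
        ``A/2 (τ − T sin(2πτ/T) / 2π)``; v = 0 before movement onset.
        """
        t = np.asarray(t, dtype=float)
        v = np.zeros_like(t)
        t0, t1, t2 = self.onset_time_s, self.push_start_s, self.push_end_s
        Td, Tp = self.descent_duration_s, self.push_duration_s
        Ad, Ap = self.descent_peak_accel, self.push_peak_accel

        def lobe_integral(tau: np.ndarray, peak: float, T: float) -> np.ndarray:
            return peak * 0.5 * (tau - T / (2 * np.pi) * np.sin(2 * np.pi * tau / T))

        descent = (t >= t0) & (t < t1)
        v[descent] = lobe_integral(t[descent] - t0, Ad, Td)
        v_descent_end = Ad * Td / 2.0
        push = (t >= t1) & (t < t2)
        v[push] = v_descent_end + lobe_integral(t[push] - t1, Ap, Tp)
        after = t >= t2
        v[after] = v_descent_end + Ap * Tp / 2.0
        return v

    def feet_share(self, t: np.ndarray | float) -> np.ndarray:
        """Smooth feet-share function s(t): static → dip → rise to end share."""
        t = np.asarray(t, dtype=float)
        t0, t1, t2 = self.onset_time_s, self.push_start_s, self.push_end_s
        t_rise = t2 - self.share_rise_duration_s
        s0, s_min, s_end = (
            self.static_feet_share,
            self.min_feet_share,
            self.feet_end_share,
        )
        s = np.full_like(t, s0)
        falling = (t >= t0) & (t < t1)
        s[falling] = s0 + (s_min - s0) * _smoothstep((t[falling] - t0) / (t1 - t0))
        low = (t >= t1) & (t < t_rise)
        s[low] = s_min
        rising = (t >= t_rise) & (t < t2)
        s[rising] = s_min + (s_end - s_min) * _smoothstep(
            (t[rising] - t_rise) / (t2 - t_rise)
        )
        s[t >= t2] = s_end
        return s

    def total_force(self, t: np.ndarray | float) -> np.ndarray:
        """Whole-body force m (g + a(t)), newtons."""
        return self.body_mass_kg * (self.gravity + self.accel(t))

    def hands_force(self, t: np.ndarray | float) -> np.ndarray:
        """Noise-free hands-platform force (1 − s(t)) · F_total(t)."""
        return (1.0 - self.feet_share(t)) * self.total_force(t)

    def feet_force(self, t: np.ndarray | float) -> np.ndarray:
        """Noise-free feet-platform force s(t) · F_total(t)."""
        return self.feet_share(t) * self.total_force(t)


@dataclass(frozen=True)
class SimGroundTruth:
    """Analytic ground truth accompanying one synthetic recording.

    ``expected_variables`` holds the eight outcome variables each calculation
    method should extract, computed from the analytic model between the same
    threshold crossings the pipeline detects (start: hands force falling 15 N
    below static; takeoff: hands force falling below 15 N).
    """

    params: SimParams
    accel_fn: Callable[[np.ndarray], np.ndarray]
    velocity_fn: Callable[[np.ndarray], np.ndarray]
    feet_share_fn: Callable[[np.ndarray], np.ndarray]
    hands_force_fn: Callable[[np.ndarray], np.ndarray]
    onset_time_s: float
    start_time_s: float
    takeoff_time_s: float
    expected_variables: dict[str, EightVariables]

    @property
    def body_weight_N(self) -> float:
        return self.params.body_mass_kg * self.params.gravity

    @property
    def feet_static_N(self) -> float:
        return self.params.static_feet_share * self.body_weight_N


def _first_crossing(
    fn: Callable[[float], float],
    level: float,
    t_lo: float,
    t_hi: float,
    coarse: int = 4000,
) -> float:
    """First time in [t_lo, t_hi] where fn crosses below ``level``.

    Scans a coarse grid for the first sign change of ``fn - level`` and
    refines it with Brent's method.
    """
    grid = np.linspace(t_lo, t_hi, coarse)
    values = np.asarray(fn(grid)) - level
    if values[0] < 0:
        return t_lo
    below = np.flatnonzero(values < 0)
    if below.size == 0:
        raise SimulationInfeasibleError(
            f"function never crosses below {level:g} in [{t_lo:g}, {t_hi:g}]"
        )
    idx = below[0]
    return float(brentq(lambda t: float(fn(t)) - level, grid[idx - 1], grid[idx]))


def _expected_variables(
    params: SimParams, t_start: float, t_end: float, oversample_hz: float = 10000.0
) -> dict[str, EightVariables]:
    """Outcome variables from the analytic model, per method.

    Two-platform velocity uses the closed-form antiderivative; phase means
    and the one-platform correction integral are evaluated on a dense
    (default 10 kHz) grid of the analytic functions, independent of the
    pipeline's sample grid.
    """
    m, g = params.body_mass_kg, params.gravity
    bw = m * g
    feet_static = params.static_feet_share * bw

    t = np.linspace(t_start, t_end, max(int((t_end - t_start) * oversample_hz), 200))
    f_total = params.total_force(t)
    feet = params.feet_force(t)
    hands = params.hands_force(t)
    v_two = params.velocity(t) - float(params.velocity(t_start))
    v_one = v_two + cumulative_trapezoid(feet_static - feet, t, initial=0.0) / m

    peak_hands = float(np.max(hands)) / bw
    out: dict[str, EightVariables] = {}
    for method, force, velocity, mean_feet in (
        ("two_platform", f_total, v_two, float(np.trapezoid(feet, t)) / (t_end - t_start)),
        ("one_platform", hands + feet_static, v_one, feet_static),
    ):
        power = force * velocity
        peak_power_idx = int(np.argmax(power))
        out[method] = EightVariables(
            peak_hands_grf_BW=peak_hands,
            peak_wholebody_grf_BW=float(np.max(force)) / bw,
            peak_wholebody_velocity_mps=float(np.max(velocity)),
            peak_wholebody_power_WperBW=float(np.max(power)) / bw,
            feet_grf_start_BW=feet_static / bw,
            mean_feet_grf_BW=mean_feet / bw,
            wholebody_grf_at_peak_power_BW=float(force[peak_power_idx]) / bw,
            wholebody_velocity_at_peak_power_mps=float(velocity[peak_power_idx]),
        )
    return out


def simulate_trial(
    params: SimParams | None = None,
    sampling_rate: float = 1000.0,
    *,
    participant_id: str = "S01",
    sex: str = "U",
    trial_id: str = "T1",
) -> tuple[PushUpRecording, SimGroundTruth]:
    """Generate one synthetic push-up recording plus its ground truth.

    Raises
    ------
    SimulationInfeasibleError
        If the constructed hands force never crosses the 15 N takeoff
        threshold (e.g. ``feet_end_share`` too small for the body mass).
    """
    params = params or SimParams()
    hands_end = (1.0 - params.feet_end_share) * params.body_mass_kg * params.gravity
    if hands_end >= _TAKEOFF_THRESHOLD_N:
        raise SimulationInfeasibleError(
            f"hands force at the end of the push ({hands_end:.1f} N) stays above "
            f"the {_TAKEOFF_THRESHOLD_N:g} N takeoff threshold; raise feet_end_share"
        )

    t = np.arange(int(round(params.total_duration_s * sampling_rate))) / sampling_rate
    hands = params.hands_force(t)
    feet = params.feet_force(t)
    if params.noise_sd_N > 0:
        rng = np.random.default_rng(params.seed)
        hands = hands + rng.normal(0.0, params.noise_sd_N, hands.size)
        feet = feet + rng.normal(0.0, params.noise_sd_N, feet.size)

    recording = PushUpRecording(
        hands=ForceTrace(hands, sampling_rate, "hands"),
        feet=ForceTrace(feet, sampling_rate, "feet"),
        body_mass=params.body_mass_kg,
        participant_id=participant_id,
        sex=sex,
        trial_id=trial_id,
    )

    hands_static = (1.0 - params.static_feet_share) * params.body_mass_kg * params.gravity
    start_time = _first_crossing(
        params.hands_force,
        hands_static - _TAKEOFF_THRESHOLD_N,
        params.onset_time_s,
        params.push_end_s,
    )
    takeoff_time = _first_crossing(
        params.hands_force,
        _TAKEOFF_THRESHOLD_N,
        params.push_start_s,
        params.push_end_s,
    )
    ground_truth = SimGroundTruth(
        params=params,
        accel_fn=params.accel,
        velocity_fn=params.velocity,
        feet_share_fn=params.feet_share,
        hands_force_fn=params.hands_force,
        onset_time_s=params.onset_time_s,
        start_time_s=start_time,
        takeoff_time_s=takeoff_time,
        expected_variables=_expected_variables(params, start_time, takeoff_time),
    )
    return recording, ground_truth


# --------------------------------------------------------------------------
# cohort generation
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ParamDist:
    """Truncated normal distribution for one per-participant parameter."""

    mean: float
    sd: float = 0.0
    low: float = -np.inf
    high: float = np.inf

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ConfigurationError("sd must be >= 0")
        if not self.low <= self.mean <= self.high:
            raise ConfigurationError(
                f"mean {self.mean} outside truncation range [{self.low}, {self.high}]"
            )

    def draw(self, rng: np.random.Generator) -> float:
        if self.sd == 0:
            return self.mean
        a = (self.low - self.mean) / self.sd
        b = (self.high - self.mean) / self.sd
        return float(
            truncnorm.rvs(a, b, loc=self.mean, scale=self.sd, random_state=rng)
        )


@dataclass(frozen=True)
class CohortSpec:
    """Population distributions for a simulated cohort, per sex.

    Sex-specific means follow the direction of observed sex differences:
    males are heavier, push harder and carry a smaller fraction of body
    weight on the feet (0.33 vs 0.36 at the start).
    """

    male: dict[str, ParamDist] = field(default_factory=dict)
    female: dict[str, ParamDist] = field(default_factory=dict)
    noise_sd_N: float = 5.0
    quiet_duration_s: float = 1.0
    feet_end_share: float = 0.99
    share_rise_duration_s: float = 0.12
    tail_duration_s: float = 0.3

    _PARAM_NAMES = (
        "body_mass_kg",
        "static_feet_share",
        "descent_peak_accel",
        "push_peak_accel",
        "descent_duration_s",
        "push_duration_s",
        "feet_dip_depth",
    )

    def __post_init__(self) -> None:
        for sex, dists in (("male", self.male), ("female", self.female)):
            missing = set(self._PARAM_NAMES) - set(dists)
            if missing:
                raise ConfigurationError(f"{sex} spec missing {sorted(missing)}")
            extra = set(dists) - set(self._PARAM_NAMES)
            if extra:
                raise ConfigurationError(f"{sex} spec has unknown keys {sorted(extra)}")

    def draw_params(self, sex: str, rng: np.random.Generator, seed: int) -> SimParams:
        dists = self.male if sex == "M" else self.female
        values = {name: dists[name].draw(rng) for name in self._PARAM_NAMES}
        # keep the dipped share strictly positive
        values["feet_dip_depth"] = min(
            values["feet_dip_depth"], values["static_feet_share"] - 0.05
        )
        rise = min(self.share_rise_duration_s, values["push_duration_s"])
        return SimParams(
            quiet_duration_s=self.quiet_duration_s,
            feet_end_share=self.feet_end_share,
            share_rise_duration_s=rise,
            tail_duration_s=self.tail_duration_s,
            noise_sd_N=self.noise_sd_N,
            seed=seed,
            **values,
        )

    @classmethod
    def from_mapping(cls, mapping: dict) -> "CohortSpec":
        def parse_sex(block: dict) -> dict[str, ParamDist]:
            out = {}
            for name, value in block.items():
                if isinstance(value, dict):
                    out[name] = ParamDist(**value)
                else:
                    out[name] = ParamDist(mean=float(value))
            return out

        kwargs = {}
        for key, value in mapping.items():
            if key in ("male", "female"):
                kwargs[key] = parse_sex(value)
            elif key in (
                "noise_sd_N",
                "quiet_duration_s",
                "feet_end_share",
                "share_rise_duration_s",
                "tail_duration_s",
            ):
                kwargs[key] = float(value)
            else:
                raise ConfigurationError(f"unknown cohort spec key {key!r}")
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "CohortSpec":
        with open(path) as handle:
            mapping = yaml.safe_load(handle)
        if not isinstance(mapping, dict):
            raise ConfigurationError("cohort spec file must contain a mapping")
        return cls.from_mapping(mapping)


def default_cohort_spec(noise_sd_N: float = 5.0) -> CohortSpec:
    """Population defaults for a physically active young-adult cohort."""
    male = {
        "body_mass_kg": ParamDist(79.0, 10.0, 50.0, 110.0),
        "static_feet_share": ParamDist(0.33, 0.03, 0.18, 0.46),
        "descent_peak_accel": ParamDist(-4.0, 0.5, -6.0, -2.0),
        "push_peak_accel": ParamDist(5.7, 0.5, 3.0, 8.0),
        "descent_duration_s": ParamDist(0.35, 0.04, 0.20, 0.50),
        "push_duration_s": ParamDist(0.62, 0.06, 0.40, 0.90),
        "feet_dip_depth": ParamDist(0.13, 0.02, 0.05, 0.24),
    }
    female = {
        "body_mass_kg": ParamDist(61.4, 8.0, 40.0, 90.0),
        "static_feet_share": ParamDist(0.36, 0.04, 0.20, 0.48),
        "descent_peak_accel": ParamDist(-3.0, 0.5, -5.0, -1.5),
        "push_peak_accel": ParamDist(2.8, 0.4, 1.8, 4.5),
        "descent_duration_s": ParamDist(0.35, 0.04, 0.20, 0.50),
        "push_duration_s": ParamDist(0.90, 0.08, 0.60, 1.20),
        "feet_dip_depth": ParamDist(0.085, 0.015, 0.04, 0.20),
    }
    return CohortSpec(male=male, female=female, noise_sd_N=noise_sd_N)


def simulate_cohort(
    n_per_sex: int = 17,
    population: CohortSpec | None = None,
    seed: int = 0,
    sampling_rate: float = 1000.0,
    n_trials: int = 1,
) -> list[tuple[PushUpRecording, SimGroundTruth]]:
    """Generate a cohort of synthetic participants (males first, then females).

    Per-participant parameters are drawn from ``population`` with the
    participant-parameter stream seeded by ``seed``; each trial's noise
    stream uses the derived seed ``seed + participant_index * 1000 +
    trial_index`` so trials are independent yet fully reproducible.
    """
    if n_per_sex < 1:
        raise ConfigurationError("n_per_sex must be >= 1")
    if n_trials < 1:
        raise ConfigurationError("n_trials must be >= 1")
    population = population or default_cohort_spec()
    rng = np.random.default_rng(seed)
    out: list[tuple[PushUpRecording, SimGroundTruth]] = []
    index = 0
    for sex in ("M", "F"):
        for i in range(n_per_sex):
            participant_id = f"{sex}{i + 1:02d}"
            base_params = population.draw_params(sex, rng, seed=0)
            for trial in range(n_trials):
                trial_seed = seed + index * 1000 + trial
                params = replace(base_params, seed=trial_seed)
                out.append(
                    simulate_trial(
                        params,
                        sampling_rate,
                        participant_id=participant_id,
                        sex=sex,
                        trial_id=f"T{trial + 1}",
                    )
                )
            index += 1
    return out


# --------------------------------------------------------------------------
# constructed recordings for the method-comparison inequality
# --------------------------------------------------------------------------


def make_method_comparison_recording(
    seed: int,
    constant_feet: bool = True,
    sampling_rate: float = 1000.0,
) -> PushUpRecording:
    """Randomized noiseless recording exercising the method-equivalence cases.

    With ``constant_feet=True`` the feet force is exactly constant at its
    static value, so the one- and two-platform methods must agree.  With
    ``constant_feet=False`` the feet force dips below its static value
    (never above it), the premise under which the one-platform method
    overestimates velocity pointwise.

    The hands force holds a quiet baseline, then falls smoothly to zero with
    a randomized bump on the way, guaranteeing both threshold crossings the
    phase detector needs.  These recordings are deliberately not
    force-conserving — they stress the analysis, not the physics.
    """
    rng = np.random.default_rng(seed)
    g = 9.81
    mass = rng.uniform(55.0, 90.0)
    bw = mass * g
    s0 = rng.uniform(0.28, 0.40)
    hands_static = (1.0 - s0) * bw
    feet_static = s0 * bw

    quiet_s, tail_s = 0.6, 0.2
    movement_s = rng.uniform(0.8, 1.5)
    bump = rng.uniform(0.0, 150.0)
    dip = 0.0 if constant_feet else rng.uniform(0.10, 0.45)

    n_quiet = int(round(quiet_s * sampling_rate))
    n_move = int(round(movement_s * sampling_rate))
    n_tail = int(round(tail_s * sampling_rate))
    u = np.arange(n_move) / n_move  # movement progress in [0, 1)

    hands_move = hands_static * (1.0 - _smoothstep(u)) + bump * np.sin(np.pi * u) ** 2
    hands = np.concatenate(
        [np.full(n_quiet, hands_static), hands_move, np.zeros(n_tail)]
    )
    feet_move = feet_static * (1.0 - dip * np.sin(np.pi * u) ** 2)
    feet = np.concatenate(
        [np.full(n_quiet, feet_static), feet_move, np.full(n_tail, feet_move[-1])]
    )
    return PushUpRecording(
        hands=ForceTrace(hands, sampling_rate, "hands"),
        feet=ForceTrace(feet, sampling_rate, "feet"),
        body_mass=mass,
        participant_id=f"X{seed:04d}",
        sex="U",
        trial_id="T1",
    )
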