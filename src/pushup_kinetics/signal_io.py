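"""Core data model and delimited-text I/O for force-platform recordings.

A push-up trial is a pair of synchronized vertical ground-reaction-force (GRF)
time series — one platform under the hands, one under the feet — sampled at a
common rate (typically 1000 Hz).  This module defines the in-memory containers
(:class:`ForceTrace`, :class:`PushUpRecording`, :class:`AnalysisConfig`) and
reads/writes the canonical CSV schema used by the pipeline:

* input recordings: columns ``time_s``, ``fz_hands_N`` and optionally
  ``fz_feet_N`` (one-platform acquisitions omit the feet column);
* output tables: ``variables.csv`` (one row per trial × method with the eight
  outcome variables) and per-method sample series
  (``time_s, f_total_BW, velocity_mps, power_WperBW``).

Forces are upward-positive vertical reaction forces in newtons; files are
plain delimited text with a decimal point (no locale commas).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    ConfigurationError,
    EmptyInputError,
    FormatError,
    SamplingError,
)

if TYPE_CHECKING:  # pragma: no cover - typing only
    from .kinetics import TrialAnalysis

__all__ = [
    "ForceTrace",
    "PushUpRecording",
    "AnalysisConfig",
    "DEFAULT_COLUMN_MAP",
    "read_recording",
    "write_results",
    "write_variables_table",
    "VARIABLE_COLUMNS",
]

#: canonical CSV column names for a recording
DEFAULT_COLUMN_MAP: Mapping[str, str] = {
    "time": "time_s",
    "hands": "fz_hands_N",
    "feet": "fz_feet_N",
}

#: stable column order of the eight outcome variables in output tables
VARIABLE_COLUMNS: tuple[str, ...] = (
    "peak_hands_grf_BW",
    "peak_wholebody_grf_BW",
    "peak_wholebody_velocity_mps",
    "peak_wholebody_power_WperBW",
    "feet_grf_start_BW",
    "mean_feet_grf_BW",
    "wholebody_grf_at_peak_power_BW",
    "wholebody_velocity_at_peak_power_mps",
)


@dataclass(frozen=True)
class ForceTrace:
    """A uniformly sampled vertical force time series from one platform.

    Parameters
    ----------
    samples:
        Vertical reaction force per sample, newtons, upward positive.
    sampling_rate:
        Samples per second (Hz), > 0.
    label:
        Platform role, ``"hands"`` or ``"feet"``.
    """

    samples: np.ndarray
    sampling_rate: float
    label: str = "hands"

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        if samples.ndim != 1:
            raise FormatError("force trace must be one-dimensional")
        if samples.size < 2:
            raise EmptyInputError("force trace needs at least 2 samples")
        if not np.all(np.isfinite(samples)):
            raise FormatError("force trace contains non-finite values")
        if not (self.sampling_rate > 0 and np.isfinite(self.sampling_rate)):
            raise ConfigurationError("sampling_rate must be positive")
        if self.label not in ("hands", "feet"):
            raise FormatError(f"unknown platform label {self.label!r}")
        object.__setattr__(self, "samples", samples)

    def __len__(self) -> int:
        return self.samples.size

    @property
    def dt(self) -> float:
        """Sample interval in seconds."""
        return 1.0 / self.sampling_rate

    @property
    def time(self) -> np.ndarray:
        """Time of each sample in seconds, starting at 0."""
        return np.arange(self.samples.size) / self.sampling_rate

    @property
    def duration(self) -> float:
        """Span from first to last sample in seconds."""
        return (self.samples.size - 1) / self.sampling_rate

    def with_samples(self, samples: np.ndarray) -> "ForceTrace":
        """Return a copy of this trace with new sample values."""
        return replace(self, samples=samples)


@dataclass(frozen=True)
class PushUpRecording:
    """Synchronized hands (+ optional feet) traces with participant metadata.

    ``feet`` is ``None`` for one-platform acquisitions, in which case
    ``body_mass`` must be supplied so the constant feet force can be derived
    as body weight minus the static hands force.
    """

    hands: ForceTrace
    feet: ForceTrace | None = None
    body_mass: float | None = None
    participant_id: str = "P00"
    sex: str = "U"
    trial_id: str = "T1"

    def __post_init__(self) -> None:
        if self.hands.label != "hands":
            object.__setattr__(self, "hands", replace(self.hands, label="hands"))
        if self.feet is not None:
            if self.feet.label != "feet":
                object.__setattr__(self, "feet", replace(self.feet, label="feet"))
            if len(self.feet) != len(self.hands):
                raise FormatError("hands and feet traces differ in length")
            if not np.isclose(
                self.feet.sampling_rate, self.hands.sampling_rate, rtol=1e-9
            ):
                raise FormatError("hands and feet traces differ in sampling rate")
        if self.body_mass is not None and not self.body_mass > 0:
            raise FormatError("body_mass must be positive")
        if self.sex not in ("M", "F", "U"):
            raise FormatError(f"sex must be 'M', 'F' or 'U', got {self.sex!r}")

    @property
    def sampling_rate(self) -> float:
        return self.hands.sampling_rate

    @property
    def two_platform(self) -> bool:
        """Whether both platforms were acquired."""
        return self.feet is not None

    def map_traces(self, fn) -> "PushUpRecording":
        """Apply ``fn`` to each present trace and return a new recording."""
        return replace(
            self,
            hands=fn(self.hands),
            feet=None if self.feet is None else fn(self.feet),
        )


@dataclass(frozen=True)
class AnalysisConfig:
    """Tunable parameters of the analysis pipeline.

    Defaults follow standard force-platform practice for explosive push-ups:
    a 100 Hz low-pass 4th-order zero-phase Butterworth filter, a 15 N
    threshold for movement onset (relative to the static hands force) and for
    takeoff (absolute), and a 0.5 s static window at the start of the
    recording for baselines.
    """

    gravity: float = 9.81
    filter_cutoff_hz: float = 100.0
    filter_order: int = 4
    phase_threshold_N: float = 15.0
    baseline_window_s: float = 0.5
    quiescence_sd_N: float = 10.0
    sampling_rate_expected: float = 1000.0
    delimiter: str = ","

    def __post_init__(self) -> None:
        if not self.phase_threshold_N > 0:
            raise ConfigurationError("phase_threshold_N must be > 0")
        if not self.baseline_window_s > 0:
            raise ConfigurationError("baseline_window_s must be > 0")
        if not self.filter_cutoff_hz > 0:
            raise ConfigurationError("filter_cutoff_hz must be > 0")
        if self.filter_order < 1:
            raise ConfigurationError("filter_order must be >= 1")
        if not self.gravity > 0:
            raise ConfigurationError("gravity must be > 0")
        if self.filter_cutoff_hz >= self.sampling_rate_expected / 2:
            raise ConfigurationError(
                "filter_cutoff_hz must be below the expected Nyquist frequency"
            )

    @classmethod
    def from_mapping(cls, mapping: Mapping) -> "AnalysisConfig":
        """Build a config from a (possibly nested) mapping.

        Accepts both flat dataclass field names and the nested layout used in
        YAML config files (``filter.cutoff_hz``, ``filter.order``,
        ``baseline.window_s``, ``phase.threshold_N``, ``gravity_mps2``).
        """
        flat: dict = {}
        nested_keys = {
            ("filter", "cutoff_hz"): "filter_cutoff_hz",
            ("filter", "order"): "filter_order",
            ("baseline", "window_s"): "baseline_window_s",
            ("baseline", "quiescence_sd_N"): "quiescence_sd_N",
            ("phase", "threshold_N"): "phase_threshold_N",
        }
        for key, value in mapping.items():
            if isinstance(value, Mapping):
                for sub, subval in value.items():
                    name = nested_keys.get((key, sub))
                    if name is None:
                        raise ConfigurationError(f"unknown config key {key}.{sub}")
                    flat[name] = subval
            elif key == "gravity_mps2":
                flat["gravity"] = value
            else:
                if key not in cls.__dataclass_fields__:
                    raise ConfigurationError(f"unknown config key {key!r}")
                flat[key] = value
        return cls(**flat)

    def to_dict(self) -> dict:
        return {name: getattr(self, name) for name in self.__dataclass_fields__}


def _infer_sampling_rate(time_s: np.ndarray, rel_jitter_tol: float = 0.01) -> float:
    """Infer the sampling rate from a time column.

    The column must be strictly increasing and uniform within ``rel_jitter_tol``
    relative step jitter; the rate is 1 / median(step).
    """
    steps = np.diff(time_s)
    if np.any(steps <= 0):
        raise SamplingError("time column must be strictly increasing")
    median_step = float(np.median(steps))
    if median_step <= 0:
        raise SamplingError("degenerate time column")
    max_rel_dev = float(np.max(np.abs(steps - median_step)) / median_step)
    if max_rel_dev > rel_jitter_tol:
        raise SamplingError(
            f"non-uniform time step: relative jitter {max_rel_dev:.3g} "
            f"exceeds tolerance {rel_jitter_tol:.3g}"
        )
    return 1.0 / median_step


def read_recording(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    config: AnalysisConfig | None = None,
    *,
    body_mass: float | None = None,
    participant_id: str = "P00",
    sex: str = "U",
    trial_id: str = "T1",
) -> PushUpRecording:
    """Read a recording from a delimited-text file.

    Parameters
    ----------
    path:
        Delimited text file with a header row.
    column_map:
        Maps the roles ``"time"``, ``"hands"`` and optionally ``"feet"`` to
        column names in the file.  Defaults to the canonical schema
        (``time_s``, ``fz_hands_N``, ``fz_feet_N``); a mapped feet column that
        is absent from the file yields a one-platform recording only when the
        default map is in use — an explicitly mapped missing column is an
        error.
    config:
        Supplies the delimiter and the expected sampling rate (a mismatch
        beyond 0.1% triggers a warning, not an error: the rate actually used
        is always inferred from the time column).
    """
    config = config or AnalysisConfig()
    explicit_map = column_map is not None
    cmap = dict(column_map or DEFAULT_COLUMN_MAP)
    for role in ("time", "hands"):
        if role not in cmap:
            raise FormatError(f"column_map must name the {role!r} column")

    path = Path(path)
    try:
        frame = pd.read_csv(path, sep=config.delimiter)
    except pd.errors.EmptyDataError as exc:
        raise EmptyInputError(f"{path}: no data") from exc

    for role in ("time", "hands"):
        if cmap[role] not in frame.columns:
            raise FormatError(f"{path}: missing mapped column {cmap[role]!r}")
    feet_col = cmap.get("feet")
    if feet_col is not None and feet_col not in frame.columns:
        if explicit_map:
            raise FormatError(f"{path}: missing mapped column {feet_col!r}")
        feet_col = None  # canonical feet column simply absent: one-platform file

    if len(frame) < 2:
        raise EmptyInputError(f"{path}: fewer than 2 rows")

    time_s = frame[cmap["time"]].to_numpy(dtype=float)
    rate = _infer_sampling_rate(time_s)
    if abs(rate - config.sampling_rate_expected) / config.sampling_rate_expected > 1e-3:
        warnings.warn(
            f"{path}: inferred sampling rate {rate:.6g} Hz differs from "
            f"expected {config.sampling_rate_expected:.6g} Hz",
            stacklevel=2,
        )

    hands = ForceTrace(frame[cmap["hands"]].to_numpy(dtype=float), rate, "hands")
    feet = (
        ForceTrace(frame[feet_col].to_numpy(dtype=float), rate, "feet")
        if feet_col is not None
        else None
    )
    return PushUpRecording(
        hands=hands,
        feet=feet,
        body_mass=body_mass,
        participant_id=participant_id,
        sex=sex,
        trial_id=trial_id,
    )


def write_recording(recording: PushUpRecording, path: str | Path) -> Path:
    """Write a recording in the canonical CSV schema. Returns the path."""
    path = Path(path)
    data = {
        "time_s": recording.hands.time,
        "fz_hands_N": recording.hands.samples,
    }
    if recording.feet is not None:
        data["fz_feet_N"] = recording.feet.samples
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.12g")
    return path


def write_variables_table(analyses: Sequence["TrialAnalysis"], path: str | Path) -> Path:
    """Write the per-trial variables table: one row per trial × method."""
    if not analyses:
        raise EmptyInputError("no analyses to write")
    rows = []
    for analysis in analyses:
        for result in analysis.results():
            rows.append(
                {
                    "participant_id": analysis.recording.participant_id,
                    "trial_id": analysis.recording.trial_id,
                    "sex": analysis.recording.sex,
                    "method": result.method,
                    **result.variables.as_dict(),
                }
            )
    path = Path(path)
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.12g")
    return path


def write_results(
    analyses: "TrialAnalysis" | Iterable["TrialAnalysis"],
    out_dir: str | Path,
    *,
    series: bool = True,
) -> list[Path]:
    """Write analysis results to a directory.

    Emits ``variables.csv`` (one row per trial × method, eight variable
    columns) and, when ``series`` is true, one
    ``series_<participant>_<trial>_<method>.csv`` per method result with the
    body-weight-normalized sample series.  Values are printed with 12
    significant digits so a round-trip read recovers them to better than 1e-9
    relative.

    Returns the list of files written.
    """
    from .kinetics import TrialAnalysis  # deferred: avoids import cycle

    if isinstance(analyses, TrialAnalysis):
        analyses = [analyses]
    analyses = list(analyses)
    if not analyses:
        raise EmptyInputError("no analyses to write")

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = [write_variables_table(analyses, out_dir / "variables.csv")]
    if series:
        for analysis in analyses:
            for result in analysis.results():
                name = (
                    f"series_{analysis.recording.participant_id}"
                    f"_{analysis.recording.trial_id}_{result.method}.csv"
                )
                frame = pd.DataFrame(
                    {
                        "time_s": result.time_s,
                        "f_total_BW": result.total_force_BW,
                        "velocity_mps": result.velocity,
                        "power_WperBW": result.power_BW,
                    }
                )
                target = out_dir / name
                frame.to_csv(target, index=False, float_format="%.12g")
                written.append(target)
    return written
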