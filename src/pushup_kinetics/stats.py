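"""Method-comparison and sex-comparison statistics.

Implements the statistical layer used to compare the one- and two-platform
calculation methods and the sexes: paired and independent (pooled-variance)
t-tests with 95% confidence intervals, Cohen's d with interpretation bands
(trivial < 0.20 ≤ small < 0.50 ≤ moderate < 0.80 ≤ large), Spearman/Pearson
correlation with strength bands (minor ≤ 0.30 < moderate ≤ 0.50 < large
≤ 0.70 < very large ≤ 0.90 < perfect ≤ 1), ordinary least-squares simple
regression, and Shapiro–Wilk normality (reported, never gating).

Cohen's d uses the pooled form ``|m_a − m_b| / sqrt((sd_a² + sd_b²) / 2)``
for both paired and independent comparisons; a difference-score variant
(``|mean(diff)| / sd(diff)``) is available for paired data via
:func:`cohens_d_paired`.

:func:`build_comparison` assembles the per-variable comparison table for a
cohort of analyzed trials: per-participant trial means are computed first
(avoiding pseudo-replication), method comparisons use paired tests plus the
between-method correlation/regression, and sex comparisons use independent
tests on the two-platform values.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import (
    StatisticsError,
    UndefinedCorrelationError,
    UndefinedEffectSizeError,
)
from .signal_io import VARIABLE_COLUMNS

__all__ = [
    "TTestResult",
    "EffectSize",
    "CorrelationResult",
    "RegressionResult",
    "ComparisonTable",
    "paired_t",
    "independent_t",
    "cohens_d",
    "cohens_d_paired",
    "d_band",
    "r_band",
    "correlate",
    "simple_regression",
    "shapiro_normality",
    "build_comparison",
    "aggregate_trials",
]

ALPHA = 0.05

#: variables whose between-method comparison is undefined (identical by
#: construction across methods), left blank in the comparison table
METHOD_INVARIANT_VARIABLES = frozenset(
    {"peak_hands_grf_BW", "feet_grf_start_BW"}
)


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: int
    p: float
    mean_diff: float
    ci_low: float
    ci_high: float
    degenerate: bool = False  # zero variance of the differences; p undefined


@dataclass(frozen=True)
class EffectSize:
    d: float
    band: str


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p: float
    band: str
    method: str


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float

    def predict(self, x: float | np.ndarray) -> float | np.ndarray:
        return self.slope * np.asarray(x) + self.intercept


def _as_array(x: Sequence[float], name: str, n_min: int) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise StatisticsError(f"{name} must be one-dimensional")
    if arr.size < n_min:
        raise StatisticsError(f"{name} needs at least {n_min} values, got {arr.size}")
    if not np.all(np.isfinite(arr)):
        raise StatisticsError(f"{name} contains non-finite values")
    return arr


def paired_t(x: Sequence[float], y: Sequence[float]) -> TTestResult:
    """Paired t-test on the differences x − y, with the 95% CI of the mean
    difference.

    Exactly equal pairs (zero variance of differences) are flagged
    ``degenerate`` with t and p undefined (NaN).
    """
    x = _as_array(x, "x", 3)
    y = _as_array(y, "y", 3)
    if x.size != y.size:
        raise StatisticsError("paired samples must have equal length")
    diff = x - y
    n = diff.size
    mean_diff = float(np.mean(diff))
    sd_diff = float(np.std(diff, ddof=1))
    if sd_diff == 0.0:
        return TTestResult(
            t=float("nan"), df=n - 1, p=float("nan"),
            mean_diff=mean_diff, ci_low=mean_diff, ci_high=mean_diff,
            degenerate=True,
        )
    t_stat, p_value = sps.ttest_rel(x, y)
    se = sd_diff / np.sqrt(n)
    margin = sps.t.ppf(1 - ALPHA / 2, n - 1) * se
    return TTestResult(
        t=float(t_stat), df=n - 1, p=float(p_value),
        mean_diff=mean_diff, ci_low=mean_diff - margin, ci_high=mean_diff + margin,
    )


def independent_t(group_a: Sequence[float], group_b: Sequence[float]) -> TTestResult:
    """Pooled-variance two-sample t-test (equal-variance form),
    df = n_a + n_b − 2, with the 95% CI of the mean difference a − b."""
    a = _as_array(group_a, "group_a", 2)
    b = _as_array(group_b, "group_b", 2)
    df = a.size + b.size - 2
    mean_diff = float(np.mean(a) - np.mean(b))
    pooled_var = (
        (a.size - 1) * np.var(a, ddof=1) + (b.size - 1) * np.var(b, ddof=1)
    ) / df
    se = float(np.sqrt(pooled_var * (1.0 / a.size + 1.0 / b.size)))
    if se == 0.0:
        return TTestResult(
            t=float("nan"), df=df, p=float("nan"),
            mean_diff=mean_diff, ci_low=mean_diff, ci_high=mean_diff,
            degenerate=True,
        )
    t_stat, p_value = sps.ttest_ind(a, b, equal_var=True)
    margin = sps.t.ppf(1 - ALPHA / 2, df) * se
    return TTestResult(
        t=float(t_stat), df=df, p=float(p_value),
        mean_diff=mean_diff, ci_low=mean_diff - margin, ci_high=mean_diff + margin,
    )


def d_band(d: float) -> str:
    """Interpretation band for Cohen's d."""
    d = abs(d)
    if d < 0.20:
        return "trivial"
    if d < 0.50:
        return "small"
    if d < 0.80:
        return "moderate"
    return "large"


def r_band(r: float) -> str:
    """Strength band for a correlation coefficient."""
    r = abs(r)
    if r > 1.0:
        raise StatisticsError(f"|r| = {r} exceeds 1")
    if r <= 0.30:
        return "minor"
    if r <= 0.50:
        return "moderate"
    if r <= 0.70:
        return "large"
    if r <= 0.90:
        return "very large"
    return "perfect"


def cohens_d(mean_a: float, sd_a: float, mean_b: float, sd_b: float) -> EffectSize:
    """Cohen's d from group summaries: |m_a − m_b| / sqrt((sd_a² + sd_b²)/2)."""
    if sd_a < 0 or sd_b < 0:
        raise StatisticsError("standard deviations must be >= 0")
    if sd_a == 0 and sd_b == 0:
        raise UndefinedEffectSizeError("Cohen's d undefined: both SDs are zero")
    d = abs(mean_a - mean_b) / np.sqrt((sd_a**2 + sd_b**2) / 2.0)
    return EffectSize(d=float(d), band=d_band(float(d)))


def cohens_d_paired(
    x: Sequence[float], y: Sequence[float], method: str = "pooled"
) -> EffectSize:
    """Cohen's d for paired samples.

    ``method="pooled"`` uses the two-group pooled form on the marginal
    summaries; ``method="difference"`` standardizes the mean difference by
    the SD of the difference scores.
    """
    x = _as_array(x, "x", 2)
    y = _as_array(y, "y", 2)
    if x.size != y.size:
        raise StatisticsError("paired samples must have equal length")
    if method == "pooled":
        return cohens_d(
            float(np.mean(x)), float(np.std(x, ddof=1)),
            float(np.mean(y)), float(np.std(y, ddof=1)),
        )
    if method == "difference":
        diff = x - y
        sd = float(np.std(diff, ddof=1))
        if sd == 0:
            raise UndefinedEffectSizeError(
                "difference-score d undefined: zero-variance differences"
            )
        d = abs(float(np.mean(diff))) / sd
        return EffectSize(d=d, band=d_band(d))
    raise StatisticsError(f"unknown Cohen's d method {method!r}")


def correlate(
    x: Sequence[float], y: Sequence[float], method: str = "spearman"
) -> CorrelationResult:
    """Spearman or Pearson correlation with the strength band attached."""
    x = _as_array(x, "x", 3)
    y = _as_array(y, "y", 3)
    if x.size != y.size:
        raise StatisticsError("x and y must have equal length")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise UndefinedCorrelationError("correlation undefined for constant input")
    if method == "spearman":
        r, p = sps.spearmanr(x, y)
    elif method == "pearson":
        r, p = sps.pearsonr(x, y)
    else:
        raise StatisticsError(f"unknown correlation method {method!r}")
    return CorrelationResult(r=float(r), p=float(p), band=r_band(float(r)), method=method)


def simple_regression(x: Sequence[float], y: Sequence[float]) -> RegressionResult:
    """Ordinary least-squares fit of y on x."""
    x = _as_array(x, "x", 3)
    y = _as_array(y, "y", 3)
    if x.size != y.size:
        raise StatisticsError("x and y must have equal length")
    if np.all(x == x[0]):
        raise StatisticsError("regression undefined for constant x")
    fit = sps.linregress(x, y)
    return RegressionResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue) ** 2,
    )


def shapiro_normality(x: Sequence[float]) -> tuple[float, float]:
    """Shapiro–Wilk normality test: (W, p).  Reported only, never gating."""
    x = _as_array(x, "x", 3)
    w, p = sps.shapiro(x)
    return float(w), float(p)


def aggregate_trials(variables: pd.DataFrame) -> pd.DataFrame:
    """Average each participant's trials per method before cohort statistics.

    Expects the long variables table (columns ``participant_id``,
    ``trial_id``, ``sex``, ``method`` plus the eight variables); returns one
    row per participant × method.
    """
    required = {"participant_id", "sex", "method"}
    missing = required - set(variables.columns)
    if missing:
        raise StatisticsError(f"variables table missing columns {sorted(missing)}")
    present = [c for c in VARIABLE_COLUMNS if c in variables.columns]
    if not present:
        raise StatisticsError("variables table has no outcome variable columns")
    return (
        variables.groupby(["participant_id", "sex", "method"], as_index=False)[present]
        .mean()
    )


@dataclass(frozen=True)
class ComparisonTable:
    """Per-variable comparison statistics with stored regression coefficients.

    ``grouping="method"`` compares the two-platform and one-platform methods
    (paired tests; mean difference = two − one) and stores, per variable, the
    regression predicting the two-platform value from the one-platform value.
    ``grouping="sex"`` compares males and females on the two-platform values
    (independent tests; mean difference = male − female).
    """

    table: pd.DataFrame
    grouping: str

    def predict_two_platform(self, value: float, variable: str) -> float:
        """Predict a two-platform value from a one-platform measurement."""
        if self.grouping != "method":
            raise StatisticsError("predictions need a method-grouping table")
        row = self.table[self.table["variable"] == variable]
        if row.empty:
            raise StatisticsError(f"unknown variable {variable!r}")
        slope = row["slope"].iloc[0]
        intercept = row["intercept"].iloc[0]
        if np.isnan(slope):
            raise StatisticsError(f"no regression stored for {variable!r}")
        return float(slope * value + intercept)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False, float_format="%.6g")


def _blank_stats() -> dict:
    return {
        "mean_diff": np.nan, "ci_low": np.nan, "ci_high": np.nan,
        "t": np.nan, "df": np.nan, "p": np.nan,
        "cohens_d": np.nan, "d_band": "",
        "r": np.nan, "r_p": np.nan, "r_band": "",
        "slope": np.nan, "intercept": np.nan, "r_squared": np.nan,
        "shapiro_p": np.nan,
    }


def build_comparison(variables: pd.DataFrame, grouping: str = "method") -> ComparisonTable:
    """Build the comparison table for a cohort's variables.

    Parameters
    ----------
    variables:
        Long table with one row per trial × method (``participant_id``,
        ``trial_id``, ``sex``, ``method`` and the eight variable columns).
    grouping:
        ``"method"`` or ``"sex"`` (sex comparison uses the two-platform
        values only).

    Variables that are identical across methods by construction (peak hands
    GRF, feet GRF at the start) are emitted with their descriptive columns
    filled and all comparison statistics blank.
    """
    per_participant = aggregate_trials(variables)
    present = [c for c in VARIABLE_COLUMNS if c in per_participant.columns]
    rows = []

    if grouping == "method":
        methods = set(per_participant["method"])
        if not {"two_platform", "one_platform"} <= methods:
            raise StatisticsError(
                "method comparison needs both two_platform and one_platform rows"
            )
        wide = per_participant.pivot(
            index="participant_id", columns="method", values=present
        )
        if wide.isna().any().any():
            raise StatisticsError("unbalanced pairing: some participants lack a method")
        n = len(wide)
        if n < 3:
            raise StatisticsError("need at least 3 participants per cell")
        for variable in present:
            two = wide[(variable, "two_platform")].to_numpy()
            one = wide[(variable, "one_platform")].to_numpy()
            row = {
                "variable": variable, "n": n,
                "mean_two_platform": float(np.mean(two)),
                "sd_two_platform": float(np.std(two, ddof=1)),
                "mean_one_platform": float(np.mean(one)),
                "sd_one_platform": float(np.std(one, ddof=1)),
                **_blank_stats(),
            }
            if variable not in METHOD_INVARIANT_VARIABLES:
                ttest = paired_t(two, one)
                row.update(
                    mean_diff=ttest.mean_diff, ci_low=ttest.ci_low,
                    ci_high=ttest.ci_high, t=ttest.t, df=ttest.df, p=ttest.p,
                )
                effect = cohens_d(
                    row["mean_two_platform"], row["sd_two_platform"],
                    row["mean_one_platform"], row["sd_one_platform"],
                )
                row.update(cohens_d=effect.d, d_band=effect.band)
                corr = correlate(one, two, method="spearman")
                row.update(r=corr.r, r_p=corr.p, r_band=corr.band)
                fit = simple_regression(one, two)
                row.update(
                    slope=fit.slope, intercept=fit.intercept, r_squared=fit.r_squared
                )
                diff = two - one
                if np.ptp(diff) > 0:
                    row["shapiro_p"] = shapiro_normality(diff)[1]
            rows.append(row)
        return ComparisonTable(table=pd.DataFrame(rows), grouping="method")

    if grouping == "sex":
        two = per_participant[per_participant["method"] == "two_platform"]
        if two.empty:
            raise StatisticsError("sex comparison needs two_platform rows")
        males = two[two["sex"] == "M"]
        females = two[two["sex"] == "F"]
        if len(males) < 3 or len(females) < 3:
            raise StatisticsError("need at least 3 participants per sex")
        for variable in present:
            a = males[variable].to_numpy()
            b = females[variable].to_numpy()
            ttest = independent_t(a, b)
            effect = cohens_d(
                float(np.mean(a)), float(np.std(a, ddof=1)),
                float(np.mean(b)), float(np.std(b, ddof=1)),
            )
            row = {
                "variable": variable, "n": len(a) + len(b),
                "mean_male": float(np.mean(a)), "sd_male": float(np.std(a, ddof=1)),
                "mean_female": float(np.mean(b)), "sd_female": float(np.std(b, ddof=1)),
                **_blank_stats(),
            }
            row.update(
                mean_diff=ttest.mean_diff, ci_low=ttest.ci_low, ci_high=ttest.ci_high,
                t=ttest.t, df=ttest.df, p=ttest.p,
                cohens_d=effect.d, d_band=effect.band,
                shapiro_p=shapiro_normality(np.concatenate([a, b]))[1],
            )
            rows.append(row)
        return ComparisonTable(table=pd.DataFrame(rows), grouping="sex")

    raise StatisticsError(f"unknown grouping {grouping!r}")
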