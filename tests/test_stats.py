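"""Comparison statistics: hand-computed oracles, published worked examples,
and calibration under simulation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from pushup_kinetics import (
    analyze_trial,
    build_comparison,
    cohens_d,
    cohens_d_paired,
    correlate,
    default_cohort_spec,
    independent_t,
    paired_t,
    simple_regression,
    simulate_cohort,
)
from pushup_kinetics.errors import (
    StatisticsError,
    UndefinedCorrelationError,
    UndefinedEffectSizeError,
)
from pushup_kinetics.signal_io import VARIABLE_COLUMNS
from pushup_kinetics.stats import aggregate_trials, d_band, r_band


class TestPairedT:
    def test_hand_computed_example(self):
        # diffs [-1,-1,-2,-2]: mean -1.5, sd 0.5774, t = -1.5/(0.5774/2)
        result = paired_t([1, 2, 3, 4], [2, 3, 5, 6])
        assert result.mean_diff == pytest.approx(-1.5)
        assert result.t == pytest.approx(-5.196, abs=1e-3)
        assert result.df == 3

    def test_identical_samples_degenerate(self):
        result = paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert result.degenerate
        assert result.mean_diff == 0.0
        assert np.isnan(result.p)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(StatisticsError):
            paired_t([1.0, 2.0], [2.0, 3.0])

    def test_ci_matches_scipy(self):
        rng = np.random.default_rng(4)
        x, y = rng.normal(0, 1, 20), rng.normal(0.3, 1, 20)
        result = paired_t(x, y)
        scipy_ci = sps.ttest_rel(x, y).confidence_interval(0.95)
        assert result.ci_low == pytest.approx(scipy_ci.low, rel=1e-9)
        assert result.ci_high == pytest.approx(scipy_ci.high, rel=1e-9)

    def test_ci_coverage_of_known_shift(self):
        """95% CI covers the true paired shift in ~95% of replicates."""
        rng = np.random.default_rng(2024)
        delta, n, hits, reps = 0.4, 34, 0, 1000
        for _ in range(reps):
            x = rng.normal(1.0, 0.3, n)
            y = x - delta + rng.normal(0.0, 0.2, n)
            result = paired_t(x, y)
            hits += result.ci_low <= delta <= result.ci_high
        assert 0.93 <= hits / reps <= 0.97

    def test_type_one_error_calibrated(self):
        """Under the null, rejection rate at alpha = 0.05 stays in
        [0.03, 0.07] over 2000 simulated cohorts."""
        rng = np.random.default_rng(99)
        n, reps, rejections = 34, 2000, 0
        for _ in range(reps):
            x = rng.normal(1.0, 0.3, n)
            y = x + rng.normal(0.0, 0.2, n)  # no systematic difference
            rejections += paired_t(x, y).p <= 0.05
        assert 0.03 <= rejections / reps <= 0.07


class TestIndependentT:
    def test_hand_computed_example(self):
        # pooled sd 1, SE = sqrt(2/3), t = -3/0.8165
        result = independent_t([1, 2, 3], [4, 5, 6])
        assert result.mean_diff == pytest.approx(-3.0)
        assert result.t == pytest.approx(-3.674, abs=1e-3)
        assert result.df == 4

    def test_identical_groups(self):
        result = independent_t([1.0, 2.0, 3.0], [3.0, 2.0, 1.0])
        assert result.t == pytest.approx(0.0, abs=1e-12)

    def test_small_group_rejected(self):
        with pytest.raises(StatisticsError):
            independent_t([1.0], [2.0, 3.0])

    def test_null_type_one_error(self):
        rng = np.random.default_rng(7)
        rejections = sum(
            independent_t(rng.normal(0, 1, 17), rng.normal(0, 1, 17)).p <= 0.05
            for _ in range(1000)
        )
        assert 0.03 <= rejections / 1000 <= 0.07


class TestCohensD:
    @pytest.mark.parametrize(
        "summary_a, summary_b, expected",
        [
            # published method-comparison rows (two- vs one-platform)
            ((0.90, 0.23), (1.39, 0.37), 1.59),
            ((1.44, 0.21), (1.46, 0.22), 0.09),
            ((1.18, 0.06), (1.19, 0.05), 0.18),
            # published sex-comparison rows (male vs female, two-platform)
            ((1.58, 0.18), (1.28, 0.11), 2.01),
            ((1.24, 0.16), (0.81, 0.20), 2.37),
            ((0.28, 0.03), (0.33, 0.04), 1.41),
            ((1.24, 0.05), (1.16, 0.05), 1.60),
        ],
    )
    def test_published_worked_examples(self, summary_a, summary_b, expected):
        effect = cohens_d(*summary_a, *summary_b)
        assert round(effect.d, 2) == expected

    def test_equal_means_trivial(self):
        effect = cohens_d(1.0, 0.2, 1.0, 0.3)
        assert effect.d == 0.0
        assert effect.band == "trivial"

    def test_both_sds_zero_undefined(self):
        with pytest.raises(UndefinedEffectSizeError):
            cohens_d(1.0, 0.0, 2.0, 0.0)

    @given(
        mean_a=st.floats(-10, 10),
        mean_b=st.floats(-10, 10),
        sd_a=st.floats(0.01, 5),
        sd_b=st.floats(0.01, 5),
        scale=st.floats(0.1, 50),
    )
    @settings(max_examples=100, deadline=None)
    def test_symmetry_and_scale_invariance(self, mean_a, mean_b, sd_a, sd_b, scale):
        forward = cohens_d(mean_a, sd_a, mean_b, sd_b).d
        assert cohens_d(mean_b, sd_b, mean_a, sd_a).d == pytest.approx(forward)
        scaled = cohens_d(mean_a * scale, sd_a * scale, mean_b * scale, sd_b * scale).d
        assert scaled == pytest.approx(forward, rel=1e-9)

    def test_difference_score_variant(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([2.0, 3.0, 5.0, 6.0])
        effect = cohens_d_paired(x, y, method="difference")
        # |mean diff| / sd(diff) = 1.5 / 0.5774
        assert effect.d == pytest.approx(2.598, abs=1e-3)

    def test_band_thresholds(self):
        assert d_band(0.19) == "trivial"
        assert d_band(0.20) == "small"
        assert d_band(0.50) == "moderate"
        assert d_band(0.80) == "large"


class TestCorrelation:
    def test_identity_perfect_for_both_methods(self):
        x = np.array([1.0, 2.0, 3.0, 5.0, 8.0])
        for method in ("spearman", "pearson"):
            result = correlate(x, x, method)
            assert result.r == pytest.approx(1.0)
            assert result.band == "perfect"

    def test_monotone_nonlinear_separates_methods(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.exp(x)
        assert correlate(x, y, "spearman").r == pytest.approx(1.0)
        assert correlate(x, y, "pearson").r < 1.0

    def test_spearman_equals_pearson_on_ranks(self):
        rng = np.random.default_rng(11)
        x = rng.normal(size=5)
        y = rng.normal(size=5)

        def brute_ranks(values):  # oracle: 1-based ranks by sorting
            order = np.argsort(values)
            ranks = np.empty_like(order, dtype=float)
            ranks[order] = np.arange(1, len(values) + 1)
            return ranks

        expected = correlate(brute_ranks(x), brute_ranks(y), "pearson").r
        assert correlate(x, y, "spearman").r == pytest.approx(expected, rel=1e-12)

    def test_constant_input_undefined(self):
        with pytest.raises(UndefinedCorrelationError):
            correlate([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_band_thresholds(self):
        assert r_band(0.30) == "minor"
        assert r_band(0.50) == "moderate"
        assert r_band(0.70) == "large"
        assert r_band(0.90) == "very large"
        assert r_band(0.91) == "perfect"


class TestSimpleRegression:
    def test_exact_collinear_fit(self):
        x = np.array([0.0, 1.0, 2.0, 3.0])
        fit = simple_regression(x, 2 * x + 1)
        assert fit.slope == pytest.approx(2.0)
        assert fit.intercept == pytest.approx(1.0)
        assert fit.r_squared == pytest.approx(1.0)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=5)
        y = 0.7 * x + rng.normal(size=5)
        fit = simple_regression(x, y)
        design = np.column_stack([x, np.ones_like(x)])
        slope, intercept = np.linalg.solve(design.T @ design, design.T @ y)
        assert fit.slope == pytest.approx(slope, rel=1e-9)
        assert fit.intercept == pytest.approx(intercept, rel=1e-9)
        # the fitted line passes through the centroid
        assert fit.slope * np.mean(x) + fit.intercept == pytest.approx(
            np.mean(y), rel=1e-9
        )

    def test_r2_equals_pearson_squared(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=30)
        y = 0.5 * x + rng.normal(size=30)
        fit = simple_regression(x, y)
        r = correlate(x, y, "pearson").r
        assert fit.r_squared == pytest.approx(r**2, abs=1e-12)

    def test_uncorrelated_noise_r2_near_zero(self):
        rng = np.random.default_rng(8)
        values = [
            simple_regression(rng.normal(size=50), rng.normal(size=50)).r_squared
            for _ in range(200)
        ]
        assert np.mean(values) < 0.05

    def test_constant_x_rejected(self):
        with pytest.raises(StatisticsError):
            simple_regression([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


def cohort_variables(n_per_sex=6, noise=0.0, seed=21) -> pd.DataFrame:
    spec = default_cohort_spec(noise_sd_N=noise)
    rows = []
    for recording, _ in simulate_cohort(n_per_sex=n_per_sex, population=spec, seed=seed):
        analysis = analyze_trial(recording)
        for result in analysis.results():
            rows.append(
                {
                    "participant_id": recording.participant_id,
                    "trial_id": recording.trial_id,
                    "sex": recording.sex,
                    "method": result.method,
                    **result.variables.as_dict(),
                }
            )
    return pd.DataFrame(rows)


@pytest.fixture(scope="module")
def variables():
    return cohort_variables()


class TestBuildComparison:

    def test_method_table_shape_and_blanks(self, variables):
        comparison = build_comparison(variables, grouping="method")
        table = comparison.table
        assert len(table) == 8
        assert list(table["variable"]) == list(VARIABLE_COLUMNS)
        # variables identical across methods carry no comparison statistics
        blank = table[table["variable"].isin(
            ["peak_hands_grf_BW", "feet_grf_start_BW"]
        )]
        assert blank["p"].isna().all() and blank["cohens_d"].isna().all()
        assert blank["mean_two_platform"].notna().all()

    def test_velocity_overestimation_is_large_and_significant(self, variables):
        table = build_comparison(variables, grouping="method").table
        row = table[table["variable"] == "peak_wholebody_velocity_mps"].iloc[0]
        assert row["mean_diff"] < 0  # two-platform minus one-platform
        assert row["p"] <= 0.05
        assert row["d_band"] == "large"
        assert row["ci_high"] < 0

    def test_identical_methods_give_zero_effect(self, variables):
        forced = variables.copy()
        two = forced[forced["method"] == "two_platform"].copy()
        one = two.copy()
        one["method"] = "one_platform"
        forced = pd.concat([two, one], ignore_index=True)
        table = build_comparison(forced, grouping="method").table
        comparable = table[~table["variable"].isin(
            ["peak_hands_grf_BW", "feet_grf_start_BW"]
        )]
        assert (comparable["cohens_d"].dropna() == 0).all()

    def test_sex_table_direction(self, variables):
        table = build_comparison(variables, grouping="sex").table
        velocity = table[table["variable"] == "peak_wholebody_velocity_mps"].iloc[0]
        assert velocity["mean_diff"] > 0  # males faster
        feet_start = table[table["variable"] == "feet_grf_start_BW"].iloc[0]
        assert feet_start["mean_diff"] < 0  # females load the feet more

    def test_prediction_uses_stored_coefficients(self, variables):
        comparison = build_comparison(variables, grouping="method")
        row = comparison.table[
            comparison.table["variable"] == "peak_wholebody_power_WperBW"
        ].iloc[0]
        value = 1.63
        assert comparison.predict_two_platform(value, "peak_wholebody_power_WperBW") == (
            pytest.approx(row["slope"] * value + row["intercept"])
        )

    def test_unbalanced_pairing_rejected(self, variables):
        broken = variables.drop(variables.index[0])
        with pytest.raises(StatisticsError):
            build_comparison(broken, grouping="method")

    def test_unknown_grouping_rejected(self, variables):
        with pytest.raises(StatisticsError):
            build_comparison(variables, grouping="trial")

    def test_trial_aggregation_averages_before_testing(self):
        frame = pd.DataFrame(
            {
                "participant_id": ["P1"] * 4,
                "trial_id": ["T1", "T2", "T1", "T2"],
                "sex": ["M"] * 4,
                "method": ["two_platform"] * 2 + ["one_platform"] * 2,
                "peak_wholebody_velocity_mps": [0.8, 1.0, 1.3, 1.5],
            }
        )
        aggregated = aggregate_trials(frame)
        assert len(aggregated) == 2
        assert set(aggregated["peak_wholebody_velocity_mps"]) == {0.9, 1.4}
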