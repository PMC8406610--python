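# Methods

## Signal model and pipeline

A trial is a pair of synchronized, uniformly sampled vertical GRF traces
(hands platform, feet platform; upward-positive newtons), nominally at
1000 Hz. The pipeline runs in fixed order: zero-phase low-pass filtering,
static-baseline estimation, push-up phase detection on the hands trace,
whole-body kinetics under each calculation method, and variable extraction.
Both methods share the same filtered traces, baseline and phase, so every
between-method difference is attributable to the constant-feet-force
assumption alone.

**Filtering.** 4th-order Butterworth, 100 Hz cutoff, applied forward and
backward (`scipy.signal.filtfilt`) with reflective padding. The double pass
makes the response zero-phase — detected events are not shifted — and
squares the magnitude response. No cutoff correction is applied for the
double pass; the nominal 100 Hz is the per-pass cutoff, which keeps results
bit-for-bit reproducible from the stated parameters. At a 100 Hz cutoff the
push-up signal (content well below 20 Hz) passes essentially unchanged;
filtering an already-filtered smooth signal moves it by < 0.1%.

**Baseline.** The first 0.5 s of the recording (configurable) must be a
quiescent hold: SD of each filtered trace < 10 N, a generous bound for a
static posture that still rejects recordings that begin mid-movement. The
static hands/feet forces are the window means. With two platforms, body
weight is their sum and body mass is derived from it; with one platform,
body mass must be supplied and the static feet force is body weight minus
the static hands force. Window means (not single samples) are used for
noise immunity.

**Phase detection.** Start: first sample with hands force strictly below
(static hands force − 15 N); the static baseline is the only reference
available at movement onset. End: first sample after the start strictly
below 15 N (takeoff). First crossings at sample resolution, no
interpolation or debouncing — at 1000 Hz quantization is ≤ 1 ms and the
filtered hands force passes through the takeoff threshold monotonically.
Detection runs on the filtered trace, consistent with filtering preceding
all analysis. Phases shorter than 0.1 s are rejected as non-physiological.

**Kinetics.** Whole-body force is the sample-wise platform sum
(two-platform) or the hands force plus the constant static feet force
(one-platform). Velocity is the cumulative trapezoidal integral of
`(F_total − m g)/m` with `v = 0` at the phase start — participants hold a
static position before descending, so the stationarity assumption of the
impulse–momentum theorem is met at the detected start. Integration includes
both endpoint samples of the phase; the one-sample sensitivity at 1000 Hz is
below 0.1%. Power is the sample-wise product `F_total · v`. Peaks are maxima
of the signed (upward-positive) series, first occurrence on ties; "at peak
power" values are read at the index of the power maximum. Forces are
normalized by body weight (dimensionless BW); power is divided by body
weight in newtons (W/BW, numerically m/s). The mean feet force over the
phase uses the measured filtered feet trace for the two-platform method and
equals the static constant by construction for the one-platform method.

Two exact identities follow from linearity of the integral and are enforced
as tests: the two methods' velocities differ by the integrated feet-force
deficit, `v_one − v_two = (1/m)∫(feet_static − F_feet)dτ`; and whenever the
feet force never exceeds its static value during the phase, the one-platform
velocity dominates pointwise, fixing the direction of the peak-velocity and
peak-power bias.

## Synthetic recordings

The generator is mechanistic rather than phenomenological: it constructs the
center-of-mass acceleration and derives forces from `F = m(g + a)`, so force
conservation holds exactly and the velocity oracle is closed-form.

* **Acceleration**: zero during a 1 s quiet hold; a raised-cosine descent
  lobe (default peak −4.0 m/s², 0.35 s); a raised-cosine push lobe (default
  peak +4.4 m/s², 0.73 s). Raised cosines are continuous and differentiable
  and integrate in closed form.
* **Platform split**: a feet-share function s(t) built from cubic-smoothstep
  blends — 0.34 at rest, dipping by 0.11 through the descent and most of
  the push (the center of mass arcs forward over the fixed toes, loading the
  hands), then rising to 0.99 over the final 0.12 s so the hands unload
  through the 15 N takeoff threshold.
* **Noise**: optional white Gaussian noise per platform (default 5 N SD for
  cohorts). No platform-resonance model is included; the 100 Hz filter
  removes most realistic sensor noise regardless.

Defaults were calibrated once so a default trial lands near published
group-level values for this movement: takeoff velocity ≈ 0.91 m/s, peak
whole-body force ≈ 1.45 BW, start feet share 0.34 and phase-mean feet share
≈ 0.30. The share trajectory is underdetermined by those summary targets
(depth vs duration of the dip trade off), so the one-platform bias magnitude
of the simulator should be read as qualitative, not as a reproduction of any
subject cohort. Cohort generation draws per-participant parameters from
truncated normal distributions with sex-specific means (males: heavier,
stronger push, smaller feet share — 0.33 vs 0.36 at the start, phase means
near 0.28 vs 0.33), one root seed, and per-trial seeds derived as
`root + participant_index·1000 + trial_index`.

Ground truth per trial contains the analytic acceleration/velocity/share
functions, the configured movement onset, the threshold-crossing times found
by root-finding on the analytic hands force, and the eight variables each
method should extract, evaluated between those crossings (closed-form
velocity; dense 10 kHz quadrature for phase means and the one-platform
correction integral — independent of the pipeline's 1 kHz sample grid).

What the simulator does **not** emulate: horizontal forces and
center-of-pressure travel, platform resonance and drift, repeated push-up
cycles, landing/catch dynamics, and trial-to-trial variability within a
participant beyond sensor noise. Pipeline tests passing on synthetic data
therefore validate the computations and their invariants, not the
biological realism of any particular force trajectory.

Because a constant feet share with constant total force can never drive the
hands force through the takeoff threshold, the strictly-constant-feet and
feet-never-above-static comparison cases are generated by a separate
constructed-recording helper (`make_method_comparison_recording`) that
builds the two platform traces directly; these recordings deliberately
ignore force conservation and exercise only the analysis contracts.

## Statistics

Method comparisons use paired t-tests on per-participant values (trials are
averaged per participant first, avoiding pseudo-replication; the aggregation
rule is this package's choice). Sex comparisons use pooled-variance
independent t-tests on the two-platform values. 95% CIs are
`mean ± t(0.975, df)·SE`. Cohen's d uses the pooled two-group form
`|m_a − m_b| / sqrt((sd_a² + sd_b²)/2)` everywhere, with the customary
bands (trivial < 0.20, small < 0.50, moderate < 0.80, large ≥ 0.80); a
difference-score variant (`|mean diff| / sd(diff)`) is provided for paired
data because published worked examples are not all internally consistent
with a single formula once inputs are rounded. Correlations are Spearman by
default with strength bands at 0.30/0.50/0.70/0.90; regression is ordinary
least squares of the two-platform value on the one-platform value, with r²
reported from the OLS (Pearson) fit. Shapiro–Wilk normality is reported per
variable and never gates the analysis. Significance is α = 0.05.

Variables that are identical across methods by construction (peak hands
GRF; feet GRF at the start) are reported with descriptive columns only and
blank comparison statistics.

## Numerical choices and degenerate inputs

* Trapezoidal integration is second-order: halving the step shrinks the
  velocity error ≈ 4× on smooth inputs; at 1000 Hz the error against the
  closed form is far below 1e-4 m/s.
* Strict `<` comparisons at thresholds; a trace that touches but never
  crosses a threshold raises a detection error rather than returning a
  phase.
* Zero-variance paired differences yield a flagged degenerate t-test result
  (p undefined) instead of an exception; both-SDs-zero effect sizes and
  constant-vector correlations raise typed errors.
* Sampling rate is always inferred from the time column (median step;
  strictly increasing; ≤ 1% relative jitter); a configured expected rate
  only triggers a warning on mismatch.
* Output CSVs print 12 significant digits so write→read round-trips are
  better than 1e-9 relative.

## Problem sizes in tests

The test-suite defaults are a single ≈2.4 s trial at 1000 Hz for unit
oracles, a 34-trial noiseless cohort for ground-truth recovery, 100 seeded
constructed recordings for the equivalence/dominance properties, 1000
randomized traces for the phase-detection oracle, and 2000/1000 replicate
draws for t-test calibration — sizes chosen to estimate each property
stably while keeping the full suite in seconds.

## Known limitations

* The one-platform bias magnitude depends on the feet-share trajectory,
  which real data constrain only through two printed summary shares; the
  simulator's default bias is therefore larger than some published cohort
  means even though all calibrated summary targets match.
* Single-repetition trials only; no segmentation of consecutive push-ups,
  no landing analysis, no rate-of-force-development or flight-height
  variables.
* Regression-based prediction of two-platform values is only as
  transferable as the cohort it was fit on.
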