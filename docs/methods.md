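# Methods

This note documents the models, detection rules and numerical choices
behind `reachkin`, in the spirit of a methods appendix: what each stage
assumes, which parameters matter, and what the synthetic data can and
cannot tell you about real recordings.

## The measurement problem

A wrist-worn IMU measures specific force in its own moving frame (gravity
plus linear acceleration, in g) and angular velocity (°/s). To obtain the
clinically interpretable quantity — the resultant speed of the hand — the
pipeline must (1) know the sensor's orientation at every sample so gravity
can be removed, and (2) integrate acceleration without letting sensor bias
and noise accumulate into unbounded velocity drift. The optical reference
has the complementary problem: positions are accurate (mm) but velocity
must come from differentiating noisy, occasionally occluded marker tracks.

## IMU pipeline

### Orientation (AHRS)

Orientation is estimated by the IMU-only (no magnetometer) gradient-descent
complementary filter: the quaternion rate from the gyroscope,
q̇ = ½ q ⊗ (0, ω), is corrected each step by a unit gradient-descent step
toward the orientation whose predicted gravity direction matches the
normalized accelerometer sample, scaled by the gain β (default 0.1 rad/s,
the standard all-round value). Heading is unobservable without a
magnetometer and irrelevant here: every downstream quantity is a resultant
magnitude, so only tilt matters.

The accelerometer correction is only valid when the accelerometer points
along gravity. During a reach it does not, and following it drags the tilt
estimate toward the apparent (gravity + linear) acceleration; the leaked
gravity then integrates into a large velocity error. The correction is
therefore *rejected* while any of three dynamics indicators fires:

* accelerometer magnitude deviating from 1 g by more than 0.1 g;
* zero-phase-smoothed angular speed above 10 °/s (reaching rotates the
  forearm);
* band-passed (0.2–3 Hz) acceleration energy above
  max(0.04 g, median + 0.03 g). This catches purely horizontal reaches,
  which barely change the magnitude and need not rotate the sensor; white
  sensor noise contributes little power in this narrow band, so the gate
  separates cleanly.

All three gates are config-exposed and can be disabled. Initial tilt comes
from the mean accelerometer vector over the first 100 frames (trials start
at rest by protocol); β = 0 with an explicit initial quaternion gives pure
gyro integration for testing.

Earth-frame linear acceleration is R(q)·a − (0,0,1 g), scaled to m/s².
Gravity is subtracted *after* rotation: subtracting from the raw z-axis
would only be correct for a perfectly level sensor.

### Trimming, stationary detection, sectioning

A trial is trimmed to 100 frames either side of the detected movement.
Movement start requires angular speed > 10 °/s, or gravity-compensated
earth-frame |z| acceleration > 0.7 g, or provisional resultant velocity
> 0.1 m/s; movement end uses the laxer 5 °/s and 0.0025 m/s (setting a
sensor down without any vibration is hard, so the end test is forgiving).
The provisional velocity is a naive integral of earth-frame acceleration
with its end-to-end linear drift removed — used only to locate movement,
never for metrics.

Stationary samples (the ZUPT anchors) are detected from an acceleration
envelope: the resultant earth-frame acceleration is high-pass filtered at
0.001 Hz, rectified, and low-pass filtered at 2 Hz (2nd-order Butterworth,
zero-phase both ways). A sample is *moving* where this envelope reaches
max(0.05 g, envelope median + 0.06 g) — the median estimates the rectified
noise floor, so the threshold adapts to the sensor's noise level — or
where the smoothed angular speed reaches 10 °/s, which catches slow
reaches whose acceleration hides under the envelope's noise floor. Three
cleanup rules make the mask usable for dead reckoning: runs of either
label shorter than 0.15 s are absorbed (a mid-reach zero-crossing of
acceleration must not split a movement); movement intervals are then
dilated by 0.10 s so the anchors sit in true rest (the smoothed detectors
release a beat late); and a dwell squeezed out by the dilation keeps its
center sample pinned, preserving per-segment drift correction. These
detector parameters are not part of the published protocol; they were
calibrated on the simulator and are all config-exposed.

The analysed *center section* runs from the first run of ≥ 10 consecutive
frames with angular speed > 10 °/s to the end of the last run of ≥ 20 such
frames; the asymmetry reflects the greater end-of-trial vibration risk.

### ZUPT dead reckoning

Within each movement interval (bounded by stationary samples on both
sides — a trial that starts or ends mid-movement is rejected), velocity is
the per-axis trapezoidal integral of earth-frame acceleration with the
stationary anchor at zero. The residual velocity at the interval's end is
pure drift and is removed by subtracting a ramp linear in time — the
standard ZUPT drift model; a constant acceleration bias b over an interval
of length T then leaves at most b·T/8 mid-interval and exactly zero at the
ends. Correction is per-axis *before* the Euclidean norm (correcting the
norm would bias speed upward, since drift of either sign inflates a
magnitude). The drift model can be switched off (`drift_model: none`) for
ablation. Speed is pinned to exactly 0 on stationary samples.

## Reference pipeline

Marker gaps of 1–9 frames are filled per axis by a not-a-knot cubic spline
through the observed samples (exact for cubic trajectories); gaps of ≥ 10
frames or at a recording boundary make the trial unprocessable — the
protocol gives no rule for them, and guessing would silently corrupt
velocities. Positions are then smoothed per axis by a cubic smoothing
spline whose penalty is bisected until the residual mean square matches
the predicted-MSE target (default 5 mm²) within 1%. When an axis carries
less noise power than the target — estimated from second differences,
Var(Δ²x)/6 — matching the target would distort the true trajectory; the
smoother then falls back to the unbiased-risk (Mallows-Cp) residual level
for the estimated noise, with the smoother-matrix traces obtained from a
single Rademacher probe (the smoother matrix depends only on the sample
times and the penalty, so fitting the probe vector yields S·z). Velocity
is the first-order central difference (exact for quadratics), one-sided at
the ends, and the resultant is converted from mm/s to m/s. Finally the
reference profile is cropped, by time, to the IMU's trimmed window, so
both systems describe the same epoch despite their different rates
(200 vs 100 Hz — the two systems are never resampled onto a common grid;
metrics are computed per system at native rate and compared per trial).

## Metrics

**Peaks.** Starting at 0.1 m/s the threshold is multiplied by 1.05 for up
to 60 iterations; the first threshold yielding exactly the task's expected
count of local maxima (3 block, 3 drink, 4 pour) wins. A local maximum is
strictly greater than both neighbours (plateaus take their first sample),
and maxima closer than 0.10 s are merged keeping the highest — without the
merge, sample-level jitter on a hump's top creates spurious maxima that no
height threshold can remove. If no threshold is exact and both systems'
profiles are available, the largest threshold at which both detect the
*same* count is used for both; a lone profile falls back to the closest
count at the largest such threshold, with a warning.

**Onset/offset.** Onset is found by walking backward from the first peak
while speed stays at or above 1% (IMU) or 2% (reference) of that peak —
the start of the rise that culminates in the peak. The IMU's lower
fraction compensates its ZUPT-pinned, slightly later-rising profile. The
50 frames before the onset should average < 0.05 m/s; a violation warns
but keeps the crossing. Offset mirrors this after the last peak with 2%
(both systems) and a 75-frame trailing window. The windows are counted in
each system's native frames, so they span different durations at 100 vs
200 Hz. Movement time is (offset − onset)/rate; peak velocity is the
maximum within the window. Note that threshold-based events sit slightly
*inside* the true movement (the 1–2% crossing happens ~20–40 ms after
motion physically starts), so measured movement time under-reads the
segment-boundary definition by ~50 ms — consistently for both systems.

**SPARC.** The speed profile between onset and offset is zero-padded to
the next power of two ≥ 16× its length; the magnitude spectrum is
normalized by its DC value; the band runs from 0 to the adaptive cutoff
ω_c — the highest frequency below 20 Hz where the normalized magnitude
still reaches 5%, located by sub-bin linear interpolation so the band edge
does not jump with the FFT grid; and the metric is the negative arc length
−Σ √((Δω/ω_c)² + ΔV̂²). It is invariant to amplitude scaling and time
shifts. The 16× padding (rather than a nominal 4×) is needed for the arc
length to converge to ~10⁻⁴ of its dense-grid value. Known brittleness:
for profiles with several submovements separated by long dwells, the
spectrum is a deep comb, and small perturbations can flip a lobe across
the 5% cutoff, jumping the metric by ~0.1–0.5. This drives essentially all
the pour-task misses in the recovery experiments.

## Agreement statistics

Differences are oriented IMU − reference throughout. Pearson r uses the
standard product-moment formula (n ≥ 3, non-degenerate). ICC(2,1) —
two-way random effects, absolute agreement, single measures — comes from
the ANOVA decomposition, ICC = (MSR − MSE)/(MSR + (k−1)MSE +
(k/n)(MSC − MSE)) with k = 2, with the F-based 95% CI of McGraw & Wong;
the implementation is cross-checked against pingouin in the tests.
Bland–Altman reports bias, limits of agreement (bias ± 1.96·SD of
differences) and a method-comparison CV% (100·SD(d)/|grand mean|; the
protocol does not define its CV, so this standard choice is flagged as an
interpretation). The systematic-error check asks whether zero lies inside
the 95% CI of the *mean* difference, bias ± t₀.₉₇₅,ₙ₋₁·SD/√n; the t
quantile (→1.96 for large n) gives exact 5% type-I error at small n, which
the calibration test verifies over 1000 null replicates.

## Synthetic data

Each task is a sequence of straight-line minimum-jerk segments
p(t) = d·(10τ³ − 15τ⁴ + 6τ⁵) separated by stationary dwells, with
displacements summing to zero (the hand returns to the start). The
minimum-jerk model is the standard description of point-to-point reaching
and gives closed-form position/velocity/acceleration — hence exact ground
truth: movement time = segment durations + interior dwells, peak speed =
max 1.875·dᵢ/Tᵢ, and SPARC of the noiseless speed. Scripted wrist
rotations (minimum-jerk angle profiles about the sensor x-axis, net zero
per trial) accompany each segment; they are physically expected — reaching
pronates/supinates the forearm, pouring by ~70° — and necessary for the
angular-speed-based sectioning to operate. Default segment tables give
movement times of ≈3.15/4.20/4.70 s and peak speeds of ≈1.20/0.72/0.59 m/s
for block/drink/pour, plausible for seated reach-manipulate-return tasks;
the drink and pour travel distances are documented constants, not
measurements.

The forward models sample the analytic trajectory: the IMU at 100 Hz as
R(t)ᵀ(a + g·e_z)/g plus per-axis bias and Gaussian noise (defaults: noise
0.02 g accel, 0.5 °/s gyro, zero bias), clipped to ±4 g and ±500 °/s; the
marker at 200 Hz in mm plus 0.5 mm Gaussian noise, with optional injected
occlusions of < 10 frames. Generation is purely a function of (spec,
seed); unseeded use is an error. Batch simulation adds between-trial
variability emulating participants and repetitions: a global tempo factor
(±15%), per-segment duration jitter (8% lognormal), dwell scaling (±25%)
and a global amplitude factor (±10%, preserving closure). Without this
spread, between-trial correlation coefficients would be undefined.

What the simulator does *not* emulate: soft-tissue artefact and sensor
mounting compliance, gyro bias instability and temperature drift,
magnetometer disturbances (not used), marker mislabeling, asynchronous
clocks between the systems (trials share a clock by construction), and the
irregular, corrective sub-movement structure of impaired reaching. Passing
recovery and agreement tests on synthetic trials therefore demonstrates
the *internal* correctness of the processing chain under realistic noise,
not the device's clinical validity — that requires real paired recordings.

## Problem sizes and observed behaviour

The recovery and agreement experiments use 60 trials per task (180 paired
trials), matching a typical per-condition trial count for such protocols
and keeping a full run at a few minutes on one CPU. At the default noise
the IMU chain recovers movement time within ±100 ms, peak velocity within
±5% and SPARC within ±0.1 for ≈93–96% of trials depending on the seed
(block and drink near 100%; pour ~85%, limited by the SPARC comb-lobe
sensitivity above). Between-system correlations and ICCs exceed 0.95 for
every task and metric, and zero lies well inside every 95% agreement
interval. Two small systematic offsets are real and worth knowing about:
the IMU's movement time reads ~10–35 ms longer than the reference (the 1%
vs 2% onset fractions, plus integrated-noise ripple near the IMU's lower
threshold), and the IMU's SPARC is ~0.02–0.03 more negative on the slower
tasks (integrated sensor noise keeps roughness the smoothed reference
lacks). Both are an order of magnitude smaller than the agreement limits.

## Known limitations

* Heading is unobservable (by design); any metric requiring absolute
  direction would need a magnetometer or external reference.
* The ZUPT chain requires trials that start and end at rest and contain
  detectable stationary anchors; continuous movement without dwells would
  need a different drift model.
* The adaptive-cutoff SPARC is discontinuous in its inputs near the
  amplitude threshold; comparisons of very multi-peaked profiles inherit
  that jumpiness.
* The predicted-MSE smoothing criterion assumes roughly stationary marker
  noise within a trial.
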