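# Methods

`cutkin` estimates stance-phase lower-limb kinetics — vertical ground
reaction force (vGRF, in body weights) and six ankle/knee joint moments
(Nm/kg; sagittal, frontal, transverse per joint) — during 45° cutting
maneuvers from a single trunk-mounted IMU (200 Hz accelerometer +
gyroscope, worn between the scapulae at the EPTS vest location).  This note
documents the model, its assumptions, the tunable parameters, the synthetic
trial generator, and the numerical and design choices.

## Signal conditioning and stance segmentation

Raw IMU channels are low-pass filtered with a 4th-order Butterworth at
20 Hz; force-plate vGRF (1000 Hz) at 30 Hz.  Filtering is applied
forward-backward (zero phase), the convention in biomechanics so that
events are not shifted in time; the configured `order` is the per-pass
design order, so effective attenuation is that of an 8th-order filter.
Reference joint moments are treated as arriving precomputed from inverse
dynamics and are not re-filtered.

The analysis window is the stance phase, detected on the filtered vGRF as
the longest contiguous run of samples at or above 20 N (initial contact =
first sample of the run, toe-off = one past the last).  The longest-run
rule is robust to bounce artifacts near the threshold; ambiguity is logged.
vGRF is normalized to body weight and moments to body mass, then every
stream — IMU-side features at 200 Hz and kinetics on their own time bases —
is linearly interpolated by *time in seconds* onto a common 101-point axis
(0–100 % of stance in 1 % steps, the standard grid in gait analysis).

## Orientation estimation (quaternion EKF)

The filter state is the unit quaternion q (scalar first) rotating
sensor-frame vectors into the world frame, with a 4×4 covariance P, at
dt = 0.005 s:

* prediction: q ← normalize((I + dt/2·Ω(ω)) q), F = I + dt/2·Ω(ω),
  P ← F P Fᵀ + Q, where ω is the bias-corrected body angular velocity.
  The first-order discretization is adequate for the sensor's ±2000 °/s
  range: against the closed-form axis-angle propagator the integration
  error is ≈ 5·10⁻⁴ °/s at 90 °/s, far below the 0.5 °/s test bound.
* update: the accelerometer is compared with the gravity reference rotated
  into the sensor frame, h(q) = R(q)ᵀ(0, 0, g) with g = 9.80655 m/s²
  (configurable); H = ∂h/∂q is the full quaternion Jacobian (no small-angle
  approximation); K = P Hᵀ(H P Hᵀ + R)⁻¹; q ← normalize(q + K y);
  P updated in the Joseph-stabilized form (I−KH)P(I−KH)ᵀ + KRKᵀ and
  re-symmetrized, which keeps P positive semidefinite over long runs.

Gyroscope bias is the per-axis mean over a static calibration window
(default 0.4 s) at the start of the recording; a non-static window is
flagged by its variance.  Accelerometer samples with near-zero norm
(< 1 m/s², free fall) skip the update.  The magnetometer is deliberately
not fused: the update uses only the gravity reference, so yaw is
gyro-integrated and slowly drifts while roll/pitch are drift-corrected —
the yaw-unobservability tests assert exactly this behavior.  Euler output
follows the intrinsic Z-Y-X (yaw-pitch-roll) convention in degrees; pitch
within 0.1° of ±90° is flagged as gimbal proximity.

Noise defaults σ_q = 10⁻⁴ (process, per step) and σ_a = 0.5 m/s²
(measurement) are tuning choices validated against synthetic trajectories
with known quaternion ground truth: on 10 s sway paths the filter recovers
roll/pitch with RMSE ≈ 0.1° noise-free and ≈ 0.25° under 0.5 m/s² / 0.5 °/s
sensor noise.

## Features and regression

Each trial yields a 101×12 block: nine primary channels (triaxial
acceleration, triaxial angular velocity, roll, pitch, yaw) resampled to the
stance axis, plus three derived channels computed pointwise *after*
resampling (and after any dataset split): acceleration magnitude, angular
velocity magnitude, and tilt angle = √(roll² + pitch²) in degrees.  There
is deliberately no explicit stance-percent column — phase information
enters only implicitly through time normalization, which shapes what the
regression can learn.

One bagged regression-tree ensemble (random forest) is trained per target
(7 models), on rows pooled across training trials.  Dataset splitting is
trial-grouped (GroupShuffleSplit, 20 % of trials to the test side, i.e.
13 of 65) so no trial leaks rows across the split; the randomized
hyperparameter search draws uniformly without replacement from the
discrete grid {n_estimators: 100–300, max_depth: 8–20, min_samples_split:
2/5/10, min_samples_leaf: 1/2/4, max_features: sqrt/log2} (450 points;
note that with 12 features `sqrt` and `log2` select the same 3-feature
subsets, so the effective grid is half that) and scores candidates by mean
5-fold cross-validated R², with folds grouped by trial to mirror the outer
split's leakage philosophy (`grouped_cv=False` restores plain folds).
Scoring shares one forest across the five n_estimators values of a
tree-shape: with a fixed seed the first k trees of a larger forest are
identical to a k-tree forest, so prefix averages reproduce independent fits
bit for bit (asserted in the test suite).  Default `n_iter` is 50;
exhaustive mode (n_iter = |space|) exists for validation.  Per-target
default hyperparameters are provided for runs without a search.  Feature
importances are impurity-based (MDI), normalized to percentages summing
to 100.

## Agreement battery

Pooled over all concatenated test rows per target: R² (1 − SS_res/SS_tot),
RMSE in target units, tie-aware Spearman rank correlation with two-sided
p-value, and Bland–Altman bias with 95 % limits of agreement
(bias ± 1.96·SD of predicted − actual, SD with the n−1 denominator).
Waveform similarity uses the two-curve coefficient of multiple correlation
(Kadaba-style within-day form) per test trial:

    CMC = √(1 − [Σₜ Σ_f (Y_ft − Ȳ_t)² / (T(F−1))] / [Σₜ Σ_f (Y_ft − Ȳ)² / (FT−1)])

with F = 2 waveforms over T = 101 points.  When the within-time dispersion
exceeds the overall dispersion the radicand is negative; the value is then
reported as NaN (the complex-CMC convention) and classified "poor".  CMC
medians map onto the five standard bands — excellent ≥ 0.95, very good
≥ 0.85, good ≥ 0.75, moderate ≥ 0.65, poor below — with boundary values
assigned to the higher band.  Table 2-style metrics pool test rows; CMC is
per-trial (its distribution, not only the median, is retained in the
report).  Mean-waveform plot exports may be smoothed with a 5-point moving
average for presentation; metrics are always computed on unsmoothed data.

## Synthetic cutting-trial generator

The generator emulates the data-collection conditions the pipeline assumes:
13 participants (body mass ~ N(75.2, 7.1²) kg) × 5 cutting trials, approach
speed ~ N(4.5, 0.5²) m/s scaling waveform amplitudes, stance duration ~
U(0.20, 0.25) s, IMU at 200 Hz, force plate at 1000 Hz.  Each trial's
timeline is: 0.5 s quasi-static lead-in (for bias calibration), 0.5 s
approach with running-support oscillations, a short ballistic flight
hugging each stance edge, the stance itself, and a 0.35 s exit.

**Orientation.**  Trunk attitude follows band-limited random-phase
roll/pitch sway and slow yaw drift, ramped in after the lead-in.  The
emitted gyro is the exact kinematic inverse of the quaternion path (body
rates from analytic Euler-rate formulas, or re-integration when coupled
terms are added), which makes the bundle a ground-truth oracle for the EKF.
Test profiles (`static`, `tilt_hold`, `cutting_sway` with ±20° sway / ±30°
yaw) serve the filter tests; full trials use a milder ±5° sway and ±5° yaw
drift so that, with the sensor artifact noise (accelerometer 1.0 m/s²,
gyro 5 °/s), orientation features do not act as per-trial fingerprints —
the property that makes the zero-coupling null clean (see below).

**Kinetics.**  vGRF is a 20 N-floored, edge-tapered double bump (impact
peak near 15–25 % stance, active peak near 50–70 %, peak 2.2–2.8 BW) built
so the designed stance window and the 20 N crossing coincide exactly.
Sagittal moments are dominant single bumps that share 45 % of their shape
with the vGRF loading profile (sagittal joint loading tracks vertical
loading); frontal/transverse moments are low-amplitude biphasic templates
with deliberately larger trial-to-trial shape jitter (0.35 vs 0.08
fractional), emulating the harder non-sagittal structure.

**Coupling.**  The world-frame specific force is an affine function of the
targets — vertical g·vGRF_BW during stance, AP braking from the sagittal
moments (−2.2 and −1.8 m/s² per Nm/kg), ML from the ankle frontal moment
(2.5 m/s² per Nm/kg) — rotated into the sensor frame by the true attitude;
body angular velocity receives weak additive contributions from the
frontal/transverse moments (5–12 °/s per Nm/kg).  A single
`coupling_strength` ∈ [0, 1] scales every kinetically informative term:

* at 1 with zero noise the accelerometer-borne mapping to vGRF and the
  sagittal moments is deterministic and the pipeline must recover it
  (held-out vGRF R² > 0.95 in the acceptance tests);
* at 0 the IMU carries no information about the targets — not even through
  stance phase, because sway and approach oscillations have per-trial
  random phases and the approach oscillations fade out before contact —
  so held-out R² ≈ 0.  A subtlety worth recording: a random forest trained
  on pure-noise features still shows slightly negative held-out R²
  (≈ −0.05) because smooth per-trial feature curves produce correlated
  per-trial prediction errors; the generator's sway amplitude and artifact
  noise were chosen (measured over 10 generator seeds) to keep this null
  bias well inside |R²| < 0.1.

The gyro channels always retain the independent sway component (it *is*
the orientation trajectory), so non-sagittal recovery is partial by design
and the sagittal > non-sagittal R² ordering emerges structurally — in the
acceptance scan it holds in 10/10 generator seeds with margins of
0.09–0.23.

All randomness flows from one seed through deterministically spawned
per-trial substreams; regenerating a corpus from (config, seed) is
byte-identical.  Templates are smooth analytic bumps with jitter, not
musculoskeletal simulations: the artifact validates pipeline correctness
and signal recovery, not human physiology.  Passing tests therefore show
that the pipeline recovers kinetics when the assumed trunk–kinetics
coupling holds and degrades gracefully when it does not; they say nothing
about the absolute accuracy achievable on real athletes, where soft-tissue
artifact, sensor mounting, and true biomechanical variability are richer
than modeled here.

## Problem sizes and numerical choices

Test and acceptance runs use the default 65-trial corpus for end-to-end
checks, ten corpora for the ordering scan (with one modest in-grid forest
configuration, 100 trees / depth 10, for all targets), and a reduced
2-trial corpus with plain 5-fold CV for the exhaustive 450-point search
equivalence — sizes chosen so each check exercises the full code path at a
desk-scale budget.  Other conventions: stance windows are half-open in
samples and inclusive in time (the last in-stance sample defines toe-off
time); interpolation is linear everywhere; division-by-zero cases
(constant actuals for R²/Spearman, identical constant waveform pairs for
CMC, non-positive body mass/weight) raise explicit errors rather than
returning sentinels; CMC NaNs sort below every finite value when the
median trial is selected.

## Known limitations

Trial-grouped (not subject-grouped) validation means trials of one
participant can appear on both sides of the split; subject-independent
generalization is a separate, harder claim.  The regression is pointwise
per normalized-time sample, so sharp transients are smoothed and peak loads
underestimated — an inherent property of bagged trees on time-normalized
rows.  Yaw is unobservable without a magnetometer and drifts with gyro
noise.  The gravity constant is kept at 9.80655 m/s² for consistency with
the validated configuration; override `ekf_g` to use a different value.
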