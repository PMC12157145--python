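# Methods

This note documents the models, conventions and numerical choices behind
`monohip`, and what the synthetic cohort does and does not establish about
real gait data.

## The measurement problem

A single IMU on the lateral thigh observes the thigh segment. The sagittal
hip angle is the thigh angle relative to the pelvis, and during gait the
pelvis tilts in phase with hip flexion, so the thigh ROM is systematically
*smaller* than the hip ROM. A single-IMU measurement of hip ROM therefore
has two parts: measure the thigh ROM accurately, then predict the hip ROM
from the thigh ROM and a few covariates. Validity is judged the way
method-comparison studies judge it: Bland–Altman bias and limits of
agreement (LoA) of predicted vs reference hip ROM, with the LoA range
(upper minus lower limit, = 2 × 1.96 × SD of the differences) required to
be strictly below 27.8°. That threshold corresponds to a standard
difference of about 5° per measurement, the usual bound for clinically
interpretable joint angles; it is stored as a configurable constant and no
derivation is asserted.

## Measurement chain

**Filtering.** The gyroscope is low-pass filtered with a windowed-sinc
(Hamming) FIR applied forward and backward (zero phase, DC gain 1), cutoff
3.2 Hz. `FilterSpec` defaults to the literal "2nd-order" description of
the reference protocol; because 3 taps at 128 Hz barely attenuate, the
processing pipeline uses 50 taps. Edges are handled by reflect-padding one
filter length. A 50-tap filter at this rate has a wide transition band and
shaves a few percent off harmonics above ~2 Hz; this shows up as a small
systematic underestimate of thigh ROM that the downstream regression
absorbs into its coefficients.

**Synchronization.** Delay between two recordings is the argmax of the
Pearson-type (mean-removed, variance-normalized) cross-correlation after
resampling both signals to the faster rate; ties break toward the smallest
absolute delay. Clock drift is modelled as delay(t) = offset + slope·t by
ordinary least squares over repeated delay measurements.

**Calibration.** The thigh medio-lateral axis is the first principal axis
of the mean-removed 3-D angular velocity during walking. Sign rule, in
order: make the largest-magnitude component positive, then flip the axis
if the peak of the projected angular velocity is negative — during swing
the flexion velocity peak is the largest excursion, so this makes flexion
positive deterministically. The segment frame is completed by
Gram–Schmidt: the sensor longitudinal axis hint is orthogonalized against
the medio-lateral axis (medio-lateral first, since it is the functionally
estimated quantity), and the anterior axis is their cross product. A
warning is raised when the first component explains < 0.6 of the variance.

**Per-cycle ROM.** Strapdown: trapezoidal integration of the calibrated
medio-lateral angular velocity, restarted at zero at every heel strike
(half-open cycles [hs, next hs)), ROM = max − min of the cycle angle.
Restarting eliminates inter-cycle drift by construction; on 60-cycle noisy
trials the fitted slope of |error| vs cycle index is ~0. Sensor fusion:
quaternions are Hamilton, scalar-first, body-to-world. The complementary
filter propagates the gyroscope and rotates the estimate toward the
accelerometer gravity direction by `gain` (default 0.02) of the tilt error
per sample; the Kalman filter is an error-state design (3-state attitude
error, gravity-direction measurement, H = [v]×) whose covariances come
from the configured gyro/accelerometer noise. The sagittal angle is the
pitch of the ZYX Euler decomposition in the calibrated segment frame;
samples with |pitch| > 89.9° are flagged. `select_best_method` picks the
method with the lowest MAE against a reference thigh ROM, ties resolving
strapdown → complementary → kalman. On the synthetic cohort (no
translational acceleration) strapdown wins; that ordering is reported, not
asserted.

**Features.** Per cycle, from the filtered medio-lateral angular velocity:
mean, bias-adjusted skewness (0 if variance < 1e−12), RMS, crest factor
(max|x|/RMS; 1 if RMS ≈ 0), minimum valley, band power (mean signal power
via periodogram, Parseval-consistent with mean(x²)) and 3 dB power
bandwidth around the spectral peak (linear interpolation of the
half-power crossings, band edge if no crossing). Walking speed and leg
length come from trial metadata. Selection is two-stage: (1) for every
feature pair with |Pearson R| ≥ 0.5, drop the member less correlated with
hip ROM, processing pairs in descending pairwise |R| (lexicographic ties)
so the result is independent of column order; constant features count as
R = 0; (2) a single regression tree on standardized survivors ranks them
by normalized impurity reduction. The tree uses min_samples_leaf = 20: a
fully grown tree on a ~1000-row table attributes irreducible cycle noise
to arbitrary features, and the leaf floor is the standard guard against
that.

**Predictors.** Model objects are built from data and `fit()` returns a
results object (estimates, standard errors where defined, `summary()`).
Naive: the training mean. SLR/MLR: OLS (statsmodels). Random forest:
scikit-learn, hyperparameters = number of trees and minimum leaf size,
optional bootstrap flag. Recurrent models: NumPy implementation of simple
RNN/GRU/LSTM with a bidirectional first recurrent layer, a second
recurrent layer, two dense hidden layers, dropout after each of the four,
and a linear (regression) or softmax (classification) head; tanh
activations for regression, ReLU for classification; losses are MSE and
sparse categorical cross-entropy; optimizer is Adam. Backpropagation
through time is hand-derived and verified against central finite
differences in the test suite (tanh configurations agree to ~1e−7;
ReLU configurations are limited by the kink, not by the gradients).
Inputs are 100 × 7 cycle tensors: the strapdown sagittal angle waveform
(whose range is the measured thigh ROM) plus tri-axial acceleration and
angular velocity, each time-normalized to 100 points. Standardization
(zero mean, unit variance; per channel for tensors) is fitted on training
folds only.

**Cross-validation.** The grouping unit is the participant-side across
all visits: all cycles of one limb of one person stay together. Group
k-fold shuffles canonically sorted groups with a seed and splits them into
k near-equal folds; stratified group k-fold (scikit-learn's
StratifiedGroupKFold) additionally balances class shares. Nested CV
grid-searches over inner folds of the outer-training groups, selecting by
mean inner loss (MSE or sparse categorical cross-entropy) with strict
improvement, after stable-sorting the grid by model size so ties resolve
toward the smaller model; the winner is refitted on the full
outer-training set. Every fold set is audited: exhaustive,
non-overlapping, group-disjoint; leakage raises.

**Agreement.** Differences are predicted − reference (an underestimating
method shows a negative bias). SD uses the n−1 denominator; the 1.96
multiplier is fixed (no t-adjustment). Validity is strict:
loa_range < 27.8.

## The synthetic cohort

The generator's defaults define the study conditions; they are chosen
once, on physiological grounds, and are not tuned per experiment.

* **Population.** 25 participants × 2 sides, 1 visit, 3 trials per side
  at 0.8 / 1.2 / 1.6 m/s (slow, self-selected, fast), 8 cycles per trial
  → 1200 cycles, 50 cross-validation groups. Hip ROM base per
  participant-visit ~ N(38°, 10²) — spanning the reduced/average/normal
  classes — plus 7 °/(m/s) speed modulation; leg length ~ N(0.90, 0.11²) m.
* **Waveforms.** Each cycle is a 4-harmonic cosine series with 1/k³
  amplitude decay (sagittal thigh motion is dominated by the stride
  fundamental), random per-visit phases, per-cycle phase jitter of
  0.25 rad and stride-time CV of 3% (both within reported stride-to-stride
  variability), reflected if needed so the peak angular velocity is
  positive (swing-phase flexion), rescaled so the range equals the drawn
  ROM exactly and anchored at 0° at heel strike so consecutive cycles join
  continuously.
* **Hip–thigh link.** The thigh ROM is the exogenous driver; the hip ROM
  follows hip = 2·amp_p + 1·thigh + 7·LL + 2·WS + ε with ε ~ N(0, 2²) per
  cycle and amp_p ~ N(1.0°, 0.2²) the participant's pelvis-tilt
  amplitude. Drawing thigh first keeps ε independent of the regressors,
  so OLS recovers the generating coefficients without simultaneity bias
  (exactly at zero noise). The pelvis contribution is realised as a
  scaled copy of the hip waveform (pelvic tilt in phase with hip
  flexion), which hits the target thigh ROM in closed form. The implied
  thigh-minus-hip offset of ~−10° reproduces the qualitative signature of
  a thigh-only measurement: a clearly negative pre-prediction bias.
* **Sensor model.** The IMU is mounted with a random misalignment
  rotation (≤ 15° by default, ≤ 20° in the calibration stress test). The
  gyroscope sees the analytic thigh angular rate about the segment
  medio-lateral axis plus out-of-plane sinusoids at cycle harmonics 5 and
  6 (≤ 20% of the sagittal peak — above the sagittal band, hence
  orthogonal to it over a cycle, which keeps the PCA problem
  non-degenerate without biasing the first axis), soft-tissue ringing at
  each heel strike (damped 10 Hz oscillation, amplitude 10 deg/s, decay
  20 s⁻¹) and white noise (1 deg/s). The accelerometer sees gravity in
  the rotating misaligned sensor frame plus white noise (0.05 m/s²).
  Values are clipped to ±2000 deg/s and ±16 g; sampling is 128 Hz.
* **What is *not* modelled.** Translational acceleration of the thigh
  (the accelerometer is gravity + noise only — adequate for the fusion
  filters' gravity-referencing role, optimistic for their absolute
  accuracy), frontal/transverse joint angles, pathology-specific gait
  signatures beyond reduced ROM, magnetometers and heading, and any
  marker-based processing (reference hip ROM and gait events are inputs
  by contract).

Because hip ROM is affine in (thigh ROM, leg length, speed) *by
construction*, passing tests show that the chain — calibration,
integration, feature selection, grouped CV, agreement — is implemented
correctly and recovers a recoverable signal. They do not show that an MLR
achieves any particular LoA range on real patients: the synthetic
residual (2° per cycle) is far better behaved than soft tissue, pathology
and marker error in a clinical cohort, which is why the out-of-fold LoA
ranges here (~8°) are much smaller than published single-IMU results.
Conversely, the relative ordering the suite asserts — prediction removes
the negative thigh bias, MLR beats the naive mean, grouped folds prevent
identity leakage — is structural and transfers.

## Numerical choices and degenerate inputs

* Time-normalization is linear interpolation onto 100 points, endpoints
  preserved; cycles of < 2 samples are rejected.
* The cosine-rate strapdown oracle (ROM 200/2π ≈ 31.83°) is met to 0.05°
  at 128 Hz by the trapezoid rule; richer waveforms at these sampling
  rates carry integration errors well below 0.05°.
* The end-to-end noise-free equivalence check runs the strapdown on
  unfiltered signals: with all disturbances off, filtering would only
  inject its own passband droop into a 0.3° comparison.
* Zero-variance signals: skewness → 0, crest factor → 1; flat inputs to
  the delay estimator and constant targets for selection/regression are
  rejected with messages. Zero-norm accelerometer samples skip the fusion
  correction step.
* ROM classes are half-open ([10, 30) → 1, [30, 45) → 2, [45, ∞) → 3);
  ROM below 10° clamps to class 1 with a warning. The mapping is total
  and monotone.
* All stochastic components take explicit seeds (default 17); cohorts,
  forests and networks are bit-reproducible for a fixed seed.

## Problem sizes

The default cohort (1200 cycles, 50 groups) runs the full
simulate → features → cross-validated comparison chain in a few seconds.
The recurrent smoke-training uses 200 cycles × 30 epochs (GRU, 16 units,
~7 s on one core). These sizes are the package's study conditions: large
enough for stable agreement statistics and class coverage, small enough
that the whole suite re-runs in well under a minute of simulation time.
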