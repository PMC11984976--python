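# Methods

## Synthetic session model

A session is a contiguous tiling of 480 trials (3 s contraction + 3 s
rest each, 2880 s total) over the 4 x 5 x 8 condition grid, with the three
repetitions of a condition consecutive (the grasped object stays in place
until they are done) and the order of gestures, loads-within-gesture and
positions-within-load permuted by the schedule seed.

**EMG.**  Channel c is amplitude-modulated Gaussian noise,
`x_c(t) = (sigma_rest + env(t) * g_c) * w_c(t)`, with `w_c` unit-variance
white noise (optionally band-limited 20–450 Hz by a 4th-order zero-phase
Butterworth, re-normalised to unit variance; off by default) and a
trapezoidal envelope ramping over 0.25 s at contraction onset/offset.
The envelope gain is

    g_c = base[gesture, c] * (1 + slope_c * load)
                           * (1 + k_pos * d_pos(position, c)
                                + k_load * d_load(load, c))

clipped at zero.  `d_pos` and `d_load` are fixed unit-amplitude sinusoids
over the channel ring whose phase advances with position (resp. load
index): a deterministic, seed-independent geometry for the pattern
distortion caused by electrode shift and stabiliser co-contraction.  The
load-table phase offset (−0.175 π) makes the heavy-load and
outstretched-position distortions act along positively correlated channel
directions, so moving far in both factors compounds the mismatch instead
of letting the two sinusoids cancel.

**FMG.**  Channel c relaxes exponentially toward
`baseline_c + pattern[gesture, c] * (load and distortion terms as above)`
during contraction (τ_rise = 0.15 s) and back toward baseline during rest
(τ_decay = 0.25 s; the asymmetry is the hysteresis model), then linear
drift (default 0) and Gaussian sensor noise are added and the signal is
clipped at zero.

**Trial-to-trial variability.**  Each trial multiplies its EMG gains and
its FMG excursion above baseline by independent per-channel log-normal
factors (log-SD 0.04).  Without this term every repetition of a condition
is an exact repeat up to carrier noise, all cross-validated designs
saturate at 100 %, and the position/load orderings degenerate to ties.

### Default study conditions and why

| parameter | default | role |
|---|---|---|
| `sample_rate_hz` | 2000 | acquisition rate; makes 200/50 ms windows exactly 400/100 samples |
| `emg_base_amplitude` | 4 x 8 matrix | gesture channel patterns; power = 1.35 x key, tripod = 1.35 x pulp pinch |
| `fmg_gesture_pattern` | 4 x 8 matrix | same structure, ratio 1.5 |
| `load_gain_slope` | 4e-4 /g | amplitude grows 1.4x from 0 to 1000 g |
| `position_effect` (κ_pos) | 0.5 | position pattern-distortion magnitude |
| `load_effect` (κ_load) | 0.3 | load pattern-distortion magnitude |
| `trial_jitter_sd` | 0.04 | log-SD of per-trial channel gain jitter |
| `noise_sd_emg` / `noise_sd_fmg` | 0.05 / 0.02 | rest noise floor / FMG sensor noise |
| `fmg_rise_tau_s` / `fmg_decay_tau_s` | 0.15 / 0.25 | FMG lag; inequality = hysteresis |
| `fmg_drift_slope` | 0 | FSR drift, off by default |
| `envelope_ramp_s` | 0.25 | contraction onset/offset ramp |

The proportional strong-grasp patterns are the load-confusion mechanism:
with amplitude growing 1.4x over the load range, a heavily loaded key
grasp approaches an unloaded power grasp in feature space.  This is what
makes load transfer genuinely hard (rather than a benign rescaling) and
produces the qualitative orderings the package asserts on its own
synthetic cohort: neutral ≥ varying accuracy, transfer accuracy strictly
decreasing in each effect magnitude, and the compound Test-3 extreme at
or below the single-factor extremes.  Magnitudes were chosen once so that
those orderings are non-degenerate (away from both the 100 %-ceiling and
chance floors) on a 5-participant cohort; they target no particular
accuracy value.

### What the generator does not emulate

No motor-unit physiology or realistic EMG spectra; no electrode-skin
impedance dynamics; no fatigue trends or inter-participant anatomy
differences (participants differ only by seed); no FSR electrical
nonlinearity beyond first-order lag + drift.  Consequently, passing the
direction-of-effect suite shows that the pipeline measures such effects
correctly when present with this geometry — it says nothing quantitative
about real recordings, whose accuracies are not reproduced here.

## Segmentation

Contraction windows are half-open second intervals `[onset, offset)`;
sample index = floor(t x rate).  The retained span is centred on the
contraction-midpoint sample, with round-half-up on
`keep_fraction x duration x rate` (4200 samples at the 0.70 / 3 s / 2000 Hz
defaults; starts at sample 900 of the contraction).  Window and step must
convert to whole samples (400 and 100 at 2000 Hz), else a validation error.

Windowing runs within each repetition separately even though the three
repetitions of a condition could be concatenated first.  Per-repetition
windowing gives every window unambiguous repetition provenance — required
for leave-one-repetition-out folds — and prevents windows that straddle a
release/re-grasp boundary from leaking across folds.  The cost is 39
windows per repetition (117 per condition) instead of 123 from a pooled
6.3 s segment; the comparison designs are unaffected because all
modalities see identical windows.

## Features

MAV, RMS and WL are the textbook definitions.  ZC counts steps with
strictly opposing signs (`x_i * x_{i+1} < 0`; exact zeros are
sign-neutral) whose magnitude reaches the deadband; SSC counts interior
extrema (`(x_i - x_{i-1})(x_i - x_{i+1}) > 0`) whose larger adjacent step
reaches the deadband.  Deadbands default to 0 (the textbook variant); the
pipeline option `rest_noise_deadband` sets per-channel deadbands to
0.01 x the rest-phase EMG SD, estimated from the second half of every rest
phase of the session.  A per-session estimate was preferred over a
per-CV-fold one: rest data carries no class label, so there is nothing to
leak, and it keeps feature values independent of fold bookkeeping.

Feature order is channel-major, (MAV, WL, ZC, SSC, RMS) within channel;
the stacked vector is exactly `[EMG-40 || FMG-8]`, bit-identical to the
single-modality vectors it concatenates.  No standardisation is applied:
LDA with a shared covariance is affine-equivariant, so results would not
change; optional z-scoring exists purely for conditioning experiments.

## Classifier

LDA with per-class means, empirical priors, and pooled within-class
covariance (denominator n − K), shrunk as
`(1 − λ) S + λ tr(S)/D I` with λ = 1e-3.  The shrinkage guards the
160-class folds, where ~12 000 windows over 48 features can leave the
pooled covariance near-singular in unlucky directions; at λ = 1e-3 it is
far below the between-class scale and leaves well-posed fixtures
unchanged (asserted against the unshrunk discriminant formula).
Prediction is `argmax_k x'S⁻¹μ_k − μ_k'S⁻¹μ_k/2 + ln π_k`; ties break to
the earliest class in canonical order (gesture order key, pulp pinch,
power, tripod; condition order gesture-major, load ascending, position
1–8).  Classification granularity is the window — no majority vote across
a repetition — and fold r holds out repetition r of every condition
simultaneously.

## Evaluation designs

Test 1 (combined) uses the full condition label as the class; its
confusion matrix is accumulated over the three folds and reported in
canonical 160-class order, with the best/worst diagonal cells of the
across-participant averaged row-normalised matrix.  Test 1
(neutral/varying) restricts to (position 2, 0 g) or pools everything,
gesture as class.  Test 2 trains on all three repetitions of one cell and
tests on all three of each disjoint cell (56 transfer cells per constant
load, 20 per constant position); no hold-out is needed because train and
test conditions are disjoint.  Test 3 likewise trains on all three
neutral repetitions for the three non-neutral extremes, but scores the
neutral baseline itself by leave-one-repetition-out to avoid
train-on-test optimism.  Summaries report mean, sample SD, SE = SD/√n,
median and IQR with linear-interpolation (type-7) quartiles; with one
participant the dispersion fields are NaN.

## Statistics

The random-intercept model is fit by profiling the variance ratio
θ = σ²_u/σ²_e: per-subject covariance blocks `I + θJ` invert analytically
(Sherman–Morrison), the fixed effects have a closed-form GLS solution at
each θ, and the −2 restricted log-likelihood is minimised over log θ by
bounded 1-D search (tolerance 1e-10), with an explicit θ = 0 boundary
check.  A cell-means design matrix makes the coefficients the estimated
marginal means directly; under the balanced design they equal raw level
means (asserted to solver tolerance).  Contrast p-values use the normal
reference distribution rather than Satterthwaite degrees of freedom: with
~27 subjects the difference is a few thousandths in p and the simulated
type-I error stays ≤ 6 % at α = 0.05.  BH adjustment is applied across
the level pairs within one model.  A rank-transform option exists for
grossly non-normal accuracy distributions; summaries always include
median/IQR alongside mean/SE/SD regardless.

## Determinism and numerical notes

Every stage is a pure function of (config, seeds); seeds are explicit
(no wall-clock), and output CSVs embed the configuration hash.  Signals
are synthesised in float32 (a full session is 16 x 5.76 M samples);
features and all downstream statistics are float64.  Degenerate inputs —
empty schedules, events outside the recording, segments shorter than a
window, classes missing from a fold, empty confusion rows, unbalanced
mixed-model designs, p-values outside [0, 1] — raise labelled errors
rather than propagating NaNs.

Problem sizes used by the shipped checks: the synthetic cohorts run 3–5
participants with full 480-trial sessions at 2000 Hz; the effect-magnitude
sweeps use reduced schedules (the 8 or 8-cell condition subsets they
compare) so each sweep point stays a few seconds of compute.

## Known limitations

Single categorical fixed effect + random intercept only (no interactions,
no Satterthwaite/Kenward–Roger df); no real-data ingestion beyond the
HDF5/CSV session container; no onset detection (event timestamps are
ground truth); no frequency-domain or autoregressive features; no
majority-vote or real-time decoding.  Reported accuracies characterise
the synthetic study conditions, not any human dataset.
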