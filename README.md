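# myofuse

Hand-gesture classification from forearm biosignals degrades when the arm
moves away from the posture it was trained in (the *position effect*) and
when the hand is loaded by a grasped object.  `myofuse` is a tested,
reproducible pipeline for quantifying those effects on three sensing
modalities — surface electromyography (EMG), force myography (FMG), and
their stacked fusion (EMG+FMG) — in a grasp-and-hold protocol: 4 hand
gestures (key, pulp pinch, power, tripod) x 5 added loads (0–1000 g) x 8
reaching positions x 3 repetitions, i.e. 480 trials per participant,
recorded as 8 EMG + 8 FMG channels at 2000 Hz.

Because no public recording of this protocol exists, the package includes a
first-class synthetic-session generator whose signal model carries the
structure the analysis responds to (gesture-specific channel patterns,
load-dependent amplitude gain, deterministic position/load pattern
distortions, trial-to-trial gain jitter, FMG lag/hysteresis/drift).  It is
intended for researchers in myoelectric control and multimodal sensor
fusion who need a fully specified, seedable reference implementation of
this family of analyses.

## Method

Each 3 s contraction is reduced to its central 70 % (2.1 s) and cut into
200 ms windows with a 50 ms step (39 windows per repetition).  Per window:

* **EMG** — the Hudgins time-domain set per channel: mean absolute value
  (MAV), waveform length (WL), zero crossings (ZC), slope sign changes
  (SSC), root mean square (RMS); 8 x 5 = 40 features;
* **FMG** — per-channel MAV; 8 features;
* **EMG+FMG** — the stacked concatenation; 48 features.

Windows are classified with linear discriminant analysis (shared
covariance, shrinkage-regularised) under leave-one-repetition-out
cross-validation; accuracy is the diagonal mean of the row-normalised
confusion matrix (macro-averaged recall).  Three designs probe the
position/load effects:

1. **Test 1** — 160-class CV over every (gesture, load, position)
   combination, plus 4-gesture CV at the neutral unloaded posture
   (position 2, 0 g) versus pooled over all conditions;
2. **Test 2** — train in a single (load, position) cell, transfer to every
   other position at constant load, and to every other load at constant
   position;
3. **Test 3** — train neutral, test at the extremes: neutral, heavily
   loaded (1000 g), outstretched (position 5), and outstretched + loaded.

Accuracies per participant feed a random-intercept linear mixed model
(y_ij = β_modality + u_i + e_ij, REML), with estimated marginal means and
Benjamini–Hochberg-corrected pairwise contrasts at α = 0.05.

## Worked example

```python
from myofuse.io_cli import PipelineConfig, run_pipeline

cfg = PipelineConfig(n_participants=3, tests=(1, 3))
run_pipeline(cfg, "results/demo")
```

`results/demo/summary.csv` then contains (per scheme x modality, percent):

```
        scheme modality  mean_pct  sd_pct  se_pct  median_pct
test1_combined      emg     96.19    0.47    0.27       96.37
test1_combined  emg_fmg     97.02    0.32    0.18       97.08
test1_combined      fmg     98.82    1.20    0.69       99.40
 test1_neutral  emg_fmg    100.00    0.00    0.00      100.00
 test1_varying  emg_fmg     90.03    0.40    0.23       90.05
         test3  emg_fmg     61.57    4.93    2.84       62.50
```

Reading it: the 160-class problem (`test1_combined`) is highly separable on
these synthetic sessions; 4-gesture accuracy drops from 100 % at the
neutral posture to ~90 % when positions and loads vary
(`test1_neutral` vs `test1_varying`); and a neutral-trained classifier
collapses toward pair-confusion levels at the Test-3 extremes (~62 %
averaged over its four test cells).  `results/demo/contrasts.csv` holds the
mixed-model comparisons, e.g. for `test1_combined` the EMG-vs-FMG contrast
is −2.63 points (BH-adjusted p ≈ 1e-4) while EMG-vs-EMG+FMG is not
significant on three synthetic participants.

The same stages are exposed as a CLI (`myofuse simulate / extract /
evaluate / stats / run-all`) and as numbered drivers under `analysis/`
(simulate → extract features → classification tests → statistics), each
writing its tables under `results/`.

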