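# Methods

## The classification problem

`eegcascade` classifies which of eight motor activities a subject performed
during a fixed acquisition protocol: real or imagined ("motor imagery")
opening/closing of the left or right hand, and real or imagined flexion of
the left or right ankle.  Input is a continuous multichannel EEG recording
at 512 Hz — either a 16-channel 10–20 research montage or a single
consumer-grade FP1 electrode — together with a light-sensor trigger channel
whose 0.5 s pulses mark the boundaries of the eight contiguous 30 s tasks.

## Pipeline

1. **Band-pass filtering.** A 3rd-order Butterworth band-pass, 0.5–59 Hz,
   applied to the continuous recording before segmentation (filtering the
   continuous signal avoids edge transients inside epochs).  The 0.5 Hz
   edge is the drift remover; there is no separate detrending stage.  The
   default application is zero-phase (forward–backward, `sosfiltfilt`),
   chosen because the analysis is offline and phase distortion would bleed
   into the odd-order moment features; note the effective magnitude
   response is then the squared design response.  A causal single-pass
   mode is available.
2. **Trigger synchronisation.** Pulses are maximal runs where the trigger
   exceeds `min + 0.5 * (max - min)` for at least 0.25 s (half the nominal
   pulse width, tolerating 2x amplitude droop).  The relative threshold
   makes detection invariant to affine rescaling of the sensor.  In the
   default *shared* boundary mode consecutive tasks share a pulse
   (9 pulses for 8 tasks); a *paired* mode (16 pulses) is supported for
   protocols with distinct end-of-task squares.
3. **Epoching and trimming.** Epoch *k* spans pulse *k*'s onset to pulse
   *k+1*'s onset; 5 s are discarded from each end of every 30 s task,
   leaving the central 20 s (10,240 samples).
4. **Windowing.** The 20 s are diced into 2 s windows with 50% overlap
   (19 windows per task), each window being one classification example.
   The window length is a package choice: it is the shortest window for
   which the per-window moment estimates are stable enough to classify,
   and it yields enough examples per task for 60/20/20-style splits.
5. **Features.** Statistical moments of orders 1–10 per channel per
   window: 160 features on the 16-channel montage, 10 on FP1.  The default
   convention is *central* moments (order 1 = mean); raw and standardized
   conventions are also implemented.  A `normalize_input` flag that
   z-scores each window before computing central moments is available but
   **off** by default: per-window standardisation erases the between-window
   dispersion differences that the even-order moments carry, and those
   dispersion features are precisely what the region level of the cascade
   consumes.  Double precision accommodates order-10 central moments of
   microvolt-scale data without rescaling.
6. **Hierarchical cascade.** Seven binary random-forest machines in three
   levels: A (hand vs ankle, trained on all rows), B0/B1 (left vs right,
   trained on ground-truth hand/ankle rows), C0–C3 (real vs imagery,
   trained on ground-truth (region, side) subsets; C0 = left-hand,
   C1 = right-hand, C2 = left-ankle, C3 = right-ankle).  At inference,
   rows are routed by *predicted* upstream outputs — standard hierarchical
   practice — and the final label is the composition (region, side, mode).
   Each machine is a scikit-learn forest wrapped so that prediction is a
   hard majority vote over per-tree labels with lexicographic tie-break,
   making inference deterministic.  Training rows are canonically sorted
   by provenance before fitting, so training is invariant to row order
   under a fixed seed.
7. **Model selection.** Greedy forward feature selection per machine
   (add the feature that maximises validation accuracy of a freshly
   retrained learner; stop at `max_k = 10` or improvement `< 0.001`)
   followed by an optional grid search over forest hyperparameters on the
   selected set.  Selection results render as per-machine tables
   (machine, moments, channels — moments only for single-channel data).

## Evaluation frameworks

* **Framework 1** (within-recording): stratified 60/20/20
  train/validation/test split of one subject's recording.
* **Framework 2** (cross-session): 80/20 of the subject's first recording
  for train/validation, the entire second recording as test — overall
  40/10/50 when the recordings are equal-sized.
* **Framework 3** (cross-subject): pooled rows of the best and worst
  Framework 1 subjects split 82/18 into train/validation; all rows of
  every remaining subject are test — approximately 18/4/78 with nine
  equal subjects.  The report includes the entrywise mean of the
  per-subject row-normalised confusion matrices.

The headline metric is the **macro per-activity accuracy**: the mean of
the row-normalised diagonal of the 8x8 confusion matrix.  Splits are
stratified by the 8-class label with largest-remainder rounding, so each
class's subset counts are within one row of the exact fractions.  Splits
operate on windows; overlapping windows may cross the Framework 1
train/test boundary, mirroring a plain within-recording split.  All
randomness descends from a single master seed through named substreams.

## The synthetic study

No public recordings exist for this protocol, so the package ships a
generator whose output is the canonical test input.  Its defaults *are*
the study conditions: 9 subjects, 2 recordings each, 8 x 30 s tasks at
512 Hz with 2 s lead-in / 2.5 s lead-out, both montages, and a trigger
channel with 0.5 s pulses.

Because the classifier consumes time-domain moments, class structure is
injected directly on three cumulant axes aligned with the cascade's three
dichotomies:

* **region → gain**: ankle tasks scale the whole signal mixture by
  `sqrt(3)` (variance ratio 3);
* **side → skewness**: an asymmetric two-harmonic oscillation (10 Hz
  fundamental plus 0.6x second harmonic) of amplitude 20 uV, added
  positively for right-side tasks and negatively for left-side tasks, so
  the sides differ in shape but not in variance;
* **mode → kurtosis**: a 7 Hz train of alternating-polarity 22 ms bursts,
  amplitude 14 uV during imagery vs 6 uV during real movement
  (ratio-coded, so the within-subject contrast survives any random
  subject offset).

The shape components are deterministic waveforms with random phase; their
time-averaged moments are essentially exact within every 2 s window,
which keeps the per-window features stable enough for the single-channel
montage to classify reliably — the role the consumer-grade device plays
in the emulated study.  The stochastic components are an exact-variance
1/f Gaussian background (10 uV, spectrally flat below 6 Hz so short-window
variance estimates have enough degrees of freedom), a 60 Hz line sine
(5 uV), a random-walk drift (20 uV; removed by the 0.5 Hz high-pass), and
Poisson blink bumps (0.1/s, 25 uV, 0.3 s) confined to the frontal
channels (Fp1/Fp2/FP1).

All components are independent, so the expected per-class variance,
skewness, and excess kurtosis follow by cumulant addition
(`class_statistics_oracle`): waveform cumulants are computed numerically
from one period, the sine contributes `A^2/2` to the variance and
`-3A^4/8` to the fourth cumulant, and blinks contribute shot-noise
cumulants via Campbell's theorem (`kappa_n = rate * integral pulse^n`,
with the Hanning-bump shape integral `C(2n, n)/4^n`).  The nonstationary
drift walk is excluded from the oracle; oracle-versus-estimate tests
disable it.

**Subject and session variability** are Gaussian offsets on the three
effect axes (log-gain, skew amplitude, log-kurtosis-amplitude), scaled by
the corresponding class-effect gap: `subject_sd = 0.8` and
`session_sd = 0.1` of the gap.  Subjects therefore differ far more than
sessions of one subject, which produces the intended regime: near-perfect
within-recording classification, a marked cross-session drop, and a much
larger cross-subject drop.  Effect sizes were fixed once so that
Framework 1 sits in the 0.95–1.0 macro-accuracy band on both montages
with variability off; they are exposed in the configuration and not
intended as tuning knobs.

What the generator does **not** emulate: mu/beta event-related
(de)synchronisation, volume conduction and electrode geometry, muscle and
movement artifacts, device-specific dropouts.  Passing tests therefore
show that the pipeline recovers the structure this generative model
encodes — not that the classifier would reach the same numbers on human
EEG.

## Numerical and design notes

* Sample indices are 0-based with half-open `[onset, offset)` intervals.
* EDF I/O is a minimal native 16-bit codec (1 s records when the length
  divides evenly, a single record otherwise); physical ranges are set per
  channel from the data, so quantization error is far below 0.01 uV.
  CSV is the lossless dialect.  The test suite cross-checks the EDF
  writer against an independent reader (MNE).
* Vote ties break to the lexicographically smallest label; grid-search
  ties break to the first point in lattice order; best/worst-subject ties
  break by subject id order.
* Selection before grid search (selection uses default learner
  parameters); the framework-comparison drivers default to fixed-parameter
  forests on all features — at the scale of one recording (152 windows),
  forests handle the full feature set well, and per-machine selection is
  validated separately.
* Degenerate inputs fail loudly: empty recordings, ragged CSV rows,
  missing trigger channels, pulse-count mismatches, classes absent from a
  machine's training subset, zero-variance windows under standardized
  moments.
* Problem sizes in the shipped checks: framework comparisons use the full
  default study (9 subjects x 2 recordings) over 5 dataset seeds; the
  no-signal control uses single-subject datasets with non-overlapping
  windows, because the binomial reference interval presumes independent
  test rows.

## Known limitations

* The generative model is a stylised moment-coded EEG; its three effect
  axes are cleanly separable by construction, which real sensorimotor
  rhythms are not.
* B/C machines never see misrouted rows at training time (ground-truth
  subsets); no probability calibration, no flat 8-class baseline beyond
  the evaluation diagnostics, no artifact rejection/ICA/CSP.
* The EDF codec covers the subset of the format the package writes
  (uniform sampling rate, 16-bit, single per-channel physical range); it
  is not a general-purpose EDF library.
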