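# Methods

`physioemo` implements a multimodal physiological emotion-classification
pipeline: four simultaneously recorded channels — ECG, electrodermal
activity (EDA) and two facial surface EMGs (zygomaticus major, medial
frontalis), all at 1000 Hz — are conditioned, reduced to their most
informative 5-min interval by a compression-based information measure,
summarized as per-frame features, and classified into three emotional
conditions (neutral / fear / happy) under subject-independent and
subject-dependent evaluation protocols.  Because no public corpus with
this exact design exists, the package ships a first-class synthetic
cohort generator with full ground truth; every claim the test suite
makes is a recovery or consistency property on that generator.

## Synthetic cohort generator

Each subject contributes one session per condition.  Channels are built
from explicit event processes so that every downstream feature has a
ground-truth anchor:

* **ECG** — beats at RR intervals `RR(t) = RR0 + A_LF sin(2π·0.1 t) +
  A_HF sin(2π·0.25 t) + ε`, each rendered as a fixed sum-of-Gaussians
  P-QRS-T template; only the T amplitude (and its beat-to-beat jitter)
  and the RR schedule vary.  Units mV.
* **EDA** — a slow random-walk tonic level plus unit-peak bi-exponential
  skin-conductance responses (rise 0.75 s, decay 4 s) at Poisson times.
  Units µS.
* **EMG** — Gaussian noise band-limited to 20–450 Hz, amplitude-modulated
  (×10 under a Hann envelope) during Poisson-timed bursts kept
  non-overlapping so burst counts are exact ground truth.  Units mV.

Two session-level structures shape all channels jointly:

* a **hotspot**: a 5-min interval in which event rates and RR
  variability are multiplied by an activation factor (default 3) and
  heart rate rises mildly (gain 0.1 per unit of activation).  Its onset
  can be offset per channel by an integer number of seconds, which is
  what the lag-synchronization stage must undo.
* an **arousal curve**: a smooth unit-mean 1-Hz modulation (Gaussian
  kernel, 3-s timescale, amplitude 0.8, floored at 0.2) shared by all
  channels of a session and delayed per channel together with the
  hotspot.  It models the moment-to-moment activation that makes the
  per-channel information profiles co-vary; without shared dynamics,
  cross-channel lag estimation would be estimating the correlation of
  independent noise.

Condition effects (mean HR, LF/HF amplitudes, T amplitude and spread,
SCR rate, tonic level, per-muscle burst rates) are population means with
per-subject Gaussian offsets drawn once and shared across that
subject's sessions.  The defaults encode: fear → high HR, SCR rate,
T-wave spread and frontalis activity; happiness → zygomaticus activity
and moderate arousal; neutral → low everything.  The between-subject
spreads are deliberately comparable to the between-condition gaps
(e.g. HR: subject sd 6 bpm vs condition gaps 7–13 bpm) because the
subject-dependent-vs-independent comparison is only meaningful when
subjects are genuinely idiosyncratic.

What the generator does **not** emulate: realistic 12-lead ECG
morphology, respiration and its coupling to HRV, motion/electrode
artifacts, non-stationary baseline wander, habituation across the
session, or any correlation between a subject's self-report and their
physiology.  Tests passing on this generator therefore demonstrate that
the pipeline recovers the structure it assumes, not that the assumed
structure captures real recordings.

## Conditioning filters

ECG: Butterworth low-pass, 40 Hz cutoff.  EMG: linear-phase FIR
band-pass 20–450 Hz.  EDA: Butterworth low-pass, 5 Hz.  Orders are not
dictated by the protocol, so conventional biosignal defaults are used
(Butterworth order 4; 501 Hamming taps) and exposed as configuration.
All filters are applied zero-phase (forward–backward IIR; delay-
compensated FIR on a reflect-padded input), preserving length and event
timing — the downstream features are time-locked counts and amplitudes,
so group delay would bias them.

## Information profiles (xaFCM)

Amplitudes are clipped to the 1st–99th percentile range and uniformly
quantized into `A = 8` levels, making the measure invariant to affine
amplitude scaling.  An adaptive finite-context model over the extended
alphabet of `A**d` super-symbols estimates the probability of each
successive block of `d` symbols from the `k` preceding blocks; the
block's code length is `-log2[(c + α) / (C + α·A**d)]` with per-outcome
pseudo-count `α = 1/A**d` (unseen contexts code at the uniform
`d·log2 A` bits).  Each block is coded, then counted — the exact bit
count an adaptive arithmetic coder would emit — and bits are attributed
to the second containing the block start.  The model is reset per
channel and per session, so no information crosses condition
boundaries.

Model-size choice: defaults are `k = 2, d = 1` (64 contexts × 8
outcomes).  With large tables (e.g. `d = 2`: 4096 contexts × 64
outcomes) the counts cannot converge within a session at 1000 Hz, so
the per-second bits are dominated by the model's own learning transient
— a monotone decline that buries real activation structure and defeats
window selection.  The small default converges within seconds;
`A, k, d, α` and the clip percentiles remain configuration for users
who want a different trade-off, and the implementation is exact for any
of them (verified against a brute-force dictionary-counting oracle).

The vectorized implementation computes, for every block, the number of
prior occurrences of its (context, block) pair and of its context via
stable argsort grouping; this reproduces sequential adaptive counting
exactly (to 1e-9 in total bits) at O(n log n).

## Synchronization and window selection

Within a session the per-channel profiles co-vary; a channel may lag
the others.  The optimal integer-second lag of each channel against the
reference (ECG) maximizes the normalized cross-correlation over
±120 s, ties broken toward smaller |lag| and then toward the negative
lag; zero-variance profiles are flagged and left unshifted.  Profiles
are shifted by the modulus of the lag (left for positive, right for
negative) and trimmed to the common overlap; the same integer offsets
are later applied to the raw signals when the selected window is cut.

The 5-min window maximizing total information is found by z-scoring
each synchronized profile (so no channel dominates by absolute bit
rate), summing across channels, and sliding a 300-s window at 1-s
steps (earliest start wins ties).

Two numerical guards precede this stage in the pipeline: the first 60 s
of every profile are discarded (the adaptive coder's warm-up would
otherwise present the session start as maximally novel) and profiles
are smoothed with a 3-s moving average before lag estimation (the
per-second bit counts are shot-noise-like around the smooth activation
structure).  Both are configuration (`profile_warmup_s`,
`profile_smooth_s`).

## Features

The selected window is divided into non-overlapping 30-s or 60-s
frames.  Per frame:

* **ECG** — R peaks from a derivative–square–integrate detector
  (150-ms integration, percentile-based adaptive threshold, 200-ms
  refractory, peak refinement to the local signal maximum); heart rate
  and mean RR; Lomb–Scargle band powers of the centered RR tachogram
  over ULF (≤ 0.003 Hz), LF (0.04–0.15 Hz) and HF (0.15–0.40 Hz); and
  the median T-wave amplitude (maximum deflection 120–400 ms after R,
  relative to the PR-segment baseline).  ULF is physically
  under-resolved on frames this short; it is computed for fidelity to
  the selected feature set and mostly reflects the within-frame RR
  trend.
* **EDA** — mean tonic (< 0.05 Hz; computed on a 10-Hz decimated copy
  for numerical stability) and the count of phasic SCR peaks rising
  ≥ 0.01 µS from their preceding onset.
* **EMG** (per muscle) — mean linear envelope (10-Hz low-pass of the
  rectified signal) and pulse-onset count: upward crossings of a
  session-calibrated robust threshold (envelope median + 3 MAD) held
  for ≥ 100 ms.

Frames with fewer than 5 detected beats are dropped with a logged
reason rather than emitting NaN.  Where the selected feature set names
a signal rather than a statistic ("RR intervals", "SCR peak indexes",
"T waves"), the scalar summaries above (frame-mean RR, per-frame peak
count, median T amplitude) realize them; each is replaceable.

## Feature selection

Three-stage cascade, fitted on training data only:

1. **Correlation filter** (default |r| > 0.9): for the strongest
   correlated pair, the member with the larger mean absolute
   correlation to all remaining features is dropped; repeated until no
   pair exceeds the threshold.  Deterministic; constant features
   (undefined correlation) are left to the next stage.
2. **Variance filter**: features are min–max scaled and those with
   scaled variance below a threshold — by default the 25th percentile
   of the scaled variances, i.e. adapted to the feature space — are
   dropped; exact constants always are.
3. **Backward elimination**: starting from all features, remove the
   feature whose removal minimizes validation error (1 − macro-F1 on a
   fixed, seeded, stratified 20% split); removals continue while the
   best candidate does not increase the error (ties count as
   improvement, which is what lets exact duplicates collapse to one)
   and stop when every removal strictly hurts.  The error metric
   matches the evaluation metric by design.

All three stages are sklearn-compatible transformers; the cascade
returns a report reconstructing every drop decision.

## Evaluation

Three split conditions over the feature frames (test set: 12 of 55
subjects at full scale; 4 of 12 at desk scale):

* **(a)** subject-independent: no frame of a test subject in training;
* **(b)** one randomly chosen emotion per test subject moved wholesale
  to training, the other two kept in test;
* **(c)** 30% (floor) of each test subject's frames per emotion moved
  to training.

Class counts in train and test are balanced by seeded down-sampling to
the minimum class count, stratified by subject so no subject-emotion
cell is emptied.  Ten outer iterations redraw the test subjects; within
each training partition a 10-fold shuffle split holds out 20%, the
model fitted on the best fold (validation macro-F1) predicts the test
set, and per-class F1, sensitivity and specificity are aggregated as
mean (sd) [max min].  Feature standardization, the selection cascade
and the inner folds are computed strictly from the training partition.

Classifiers: random forests (8000 trees for single-signal and two-EMG
inputs, 10000 for the all-signal input; conventional defaults
otherwise) and MLPs with fixed hidden-layer widths per input set
(all: 28; ECG/EMG-zygomatic/EDA: 12-9-6; EMG-frontalis: 8-9; both-EMG:
10-24; 3 softmax outputs).  The MLP training regimen is not dictated by
the protocol; ReLU activations, Adam, cross-entropy, at most 500
epochs with early stopping (patience 20) are used.

## Desk-scale defaults and problem sizes

The package's desk-scale configuration — used by the test suite and by
`scripts/acceptance.py` — is 12 subjects × 3 conditions × 12-min
sessions (hotspot minutes 4–9), 4 test subjects, random forests reduced
to 500 trees, and a 50-tree seeded forest inside the elimination
wrapper (which refits O(p²) models per iteration).  The qualitative-
ordering checks evaluate random forests under conditions (a) and (c)
at 30-s frames over 10 iterations; the full 72-cell factorial
(6 signal sets × 3 conditions × 2 frame lengths × 2 classifiers) is
exercised end-to-end at a smaller test scale (6 subjects, 7-min
sessions, 50 trees, 2 iterations).  Full-scale settings (55 subjects,
30-min sessions, 8000/10000 trees) remain available through the same
configuration objects.

## Numerical choices and degenerate inputs

* Quantization of a constant signal maps everything to one symbol — a
  valid, maximally-compressible sequence, not an error.
* Cross-correlation of a zero-variance profile is undefined: lag 0 is
  returned with a degeneracy flag and the channel is not shifted.
* Window-selection ties go to the earliest start; lag ties to the
  smaller |lag|, then the negative one.
* Event times are made strictly increasing; EMG bursts are separated by
  ≥ 0.5 s so planted-count recovery is well-defined.
* The final partial second of a profile is dropped; blocks start after
  the first full context.
* Balancing never applies to an empty partition; splits reject cohorts
  in which any subject lacks one of the three conditions.

## Known limitations

* The information profile is a novelty measure under a small adaptive
  model, not a calibrated entropy estimate; absolute bit rates depend
  on `A, k, d, α`.
* Lag estimation assumes the channels share slow activation dynamics;
  on signals without common structure the estimated lags are noise
  (the degeneracy flag only catches the constant case).
* ULF band power on 30–60-s frames is a trend proxy, not ULF power.
* The generator's effect sizes are free parameters chosen to be
  plausible, not estimates from data; classification scores on the
  synthetic cohort are therefore not comparable to scores on real
  recordings.
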