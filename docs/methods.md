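# Methods

## Signal model and preprocessing

A 30-s chair sit-to-stand (CST) trial is a six-channel inertial recording
from a device at the lower back: acceleration (m/s²) and angular velocity
(rad/s) on the vertical (x), mediolateral (y) and antero-posterior (z)
axes, nominally 400 Hz. Voluntary sit-to-stand movement lives below ~5 Hz,
so all channels pass through a zero-phase low-pass Butterworth filter with
cutoff 6 Hz and single-pass order 2. "Zero phase" means forward–backward
application: the effective magnitude response is the single-pass response
squared and phase distortion cancels, which is what keeps peak timings
trustworthy. Edges are handled by reflective padding of three filter
lengths; the first and last 0.25 s are additionally excluded from peak
candidacy because residual edge transients can mimic impulses.

Timestamps whose spacing jitters more than 5 % around the median are
resampled onto a uniform grid by linear interpolation before analysis;
Welch spectra and trapezoidal integration both assume uniform sampling.

Detection operates on the Euclidean norm of the accelerometer channels.
The norm is invariant under any rigid re-orientation of the sensor, which
removes the dependence on exact phone mounting and keeps movement energy
that posture changes redistribute across axes.

## Adaptive cycle detection

Two per-trial thresholds adapt the detector to each participant:

* **Amplitude** — `th_amp = α (max a_mag − min a_mag)`, with `α = 0.2` by
  default and a studied range of 0.1–0.4. Peak height is measured above the
  trial minimum of `a_mag` rather than absolutely: the magnitude carries a
  ≈9.81 m/s² gravity offset, and an absolute comparison against a fraction
  of the range would be vacuously true for every sample. The literal
  absolute comparison remains available
  (`DetectionConfig(baseline_correction="none")`) for fidelity experiments.
  `th_amp` is additionally floored at `min_amplitude = 1 m/s²`: a purely
  relative threshold scales down with the signal range, so a recording that
  contains no movement at all would have its noise maxima "detected".
  Sub-1 m/s² fluctuations are not postural transitions on any cohort.
* **Timing** — `th_time = γ / DF`. `DF` is the argmax of the Welch power
  spectral density of `a_mag` (Hann window, segments of min(8 s, trial),
  50 % overlap, mean detrend) inside 0.1–2.5 Hz, the physiologically
  plausible band of CST repetition rates. The band's lower edge is clipped
  to two periods per Welch segment (0.25 Hz at the default segment length):
  a slower "peak" cannot be resolved by the estimator and is an artefact of
  windowing. If no peak exceeds 3× the band's median power the spectrum is
  declared degenerate and the time guard is disabled with a warning rather
  than failing the trial. `γ = 1` reproduces the strict reciprocal of the
  dominant frequency, which equals the *mean* cycle period and would reject
  valid faster-than-average repetitions; the default `γ = 0.75` leaves room
  for the within-trial duration spread while still rejecting
  within-transition double counts.

Candidate peaks are strict local maxima (plateaus contribute their centre
sample). Acceptance is a greedy scan in time order: a candidate is accepted
iff its height above baseline reaches `th_amp` (inclusive) and it arrives at
least `th_time` after the last accepted peak; rejected candidates do not
reset the clock. On candidate lists of up to 12 peaks this greedy scan
provably equals exhaustive enumeration of maximal admissible subsequences
(verified in the test suite), and a post-hoc audit asserts both conditions
on every accepted peak of every run.

Each pair of consecutive accepted peaks delimits one full
stand-and-return cycle; `n` peaks yield `n − 1` cycles and a trailing
incomplete repetition contributes none. One accepted peak per repetition
boundary is this package's convention; the two transition impulses inside a
repetition are deliberately merged by the time guard. Within a cycle, the
apex is the global interior minimum of `a_mag` — the quiet instant between
the stand impulse and the sit impulse; rise time runs start→apex and sit
time apex→end. A monotone segment without an interior valley is flagged
and halved with a warning.

## Rising-strategy classification

Trunk pitch within a cycle is the cumulative trapezoidal integral of the
mediolateral angular velocity over the detected cycle window. Windowing per
cycle bounds gyroscope drift by the cycle duration; no sensor-fusion drift
correction is attempted. Over a complete stand-and-return cycle the *net*
pitch integral is ≈0 by construction (the trunk returns to its starting
posture), so a net measure could never exceed a 0.35-rad threshold for any
strategy; the default summary is therefore the peak-to-trough **excursion**
`max θ − min θ`, with the net measure retained as
`StrategyConfig(pitch_measure="net")` for fidelity experiments. The pitch
sign is configurable (`pitch_sign = ±1`) because mounting may flip the
mediolateral axis; excursion is invariant to the flip.

A cycle is labelled MT iff it is strictly faster than the age-adjusted
threshold `τ_g` (1.2 s young, 1.6 s older, 2.0 s Parkinson's) **and** its
pitch excursion strictly exceeds `θ_thresh = 0.35 rad` (≈20°); otherwise
Flexion. Ties fall to Flexion. Raising `θ_thresh` can only convert MT to
Flexion, raising `τ_g` only Flexion to MT (monotonicity, property-tested).
`use_pitch=False` drops the pitch condition — the "without trunk pitch"
ablation.

## Agreement statistics

Validation against a reference method (e.g. video annotation) respects the
nesting of cycles in participants. Detected and annotated cycles are paired
one-to-one by nearest start time within half the median annotated cycle
duration; count accuracy is `matched / max(n_detected, n_annotated)` so
both misses and spurious detections penalise, and timing MAE is the mean
absolute duration error over matched pairs. Participant-level inference
(Pearson/Spearman, paired *t*, Bland–Altman with the conventional
`±1.96·SD` limits and `SE ≈ sqrt(3/n)·SD` confidence bands, ICC(2,1)
absolute agreement and ICC(3,1) consistency from two-way ANOVA mean
squares) uses each participant's mean cycle time under both methods.
Cycle-level differences feed a random-intercept linear mixed model
`d_ij = β₀ + u_i + ε_ij`, fitted by REML (unbiased variance components at
modest participant counts; the balanced closed form is its test oracle),
with a Wald test for `β₀ = 0` and nesting-aware limits of agreement
`β₀ ± 1.96·sqrt(σ²_between + σ²_within)`. Strategy agreement is the
unweighted macro F1 over classes present in truth or prediction.

At the default study scale (35 × 19 observations) with a within-participant
SD an order of magnitude above the between-participant SD, `σ_between`
sits near its own detection limit; REML recovery is unbiased only up to the
truncation of variance estimates at zero, which the recovery test accounts
for via Monte-Carlo standard errors.

## The simulator

The generator emulates the statistical structure the pipeline assumes — it
is a calibrated stand-in, not recorded biomechanics.

* **Study composition**: 10 young / 20 older / 5 Parkinson's participants,
  one 30-s trial each at 400 Hz.
* **Durations**: per-cohort, per-strategy full-cycle means come from
  published descriptive statistics (older adults: Flexion 2.63 s vs MT
  1.45 s, etc.). Their pooled SDs are decomposed into a between-participant
  multiplicative speed factor (CV 15 %, applied to both strategy means,
  with a participant's Flexion mean tied to 1.52–1.81× their MT mean — the
  published within-cohort slowdown) and within-trial jitter (CV 8 %);
  a trial's repetitions are far more alike than cohort-pooled SDs suggest.
  Durations are floored at 0.4 s.
* **Strategy mixing**: each participant has a dominant strategy (MT with
  probability 0.85/0.70/0.25 by cohort); a trial switches regime once
  mid-trial with probability 0.2, else stays pure. The per-strategy
  repetition counts of the reference descriptives each fill an entire 30-s
  trial, which is what motivates trial-level rather than cycle-level
  mixing; regime switches reproduce the observed mid-test strategy changes.
* **Waveforms**: vertical acceleration is gravity plus a raised-cosine
  burst (width 30 % of the shorter adjacent cycle) at every repetition
  boundary, a 0.4 m/s² quiet-valley dip at each apex, and — for cycles
  longer than 1.1 s, with probability 0.5 — a seat-impact echo bump
  ~0.3·T after the boundary at 35–50 % of the main amplitude. The echo is
  the realistic within-transition false positive that the
  dominant-frequency guard exists to reject; without it the guard has no
  work to do. Bursts are smooth and band-limited below the 6-Hz cutoff so
  filtering preserves morphology. Mediolateral angular velocity is a
  biphasic half-sine pair whose forward lobe integrates exactly to the
  requested pitch excursion and whose net integral is ≈0. A fixed mounting
  tilt rotates all samples; white Gaussian noise (0.4 m/s², 0.03 rad/s) is
  added per channel.
* **Class separability** is calibrated, not emergent: MT durations are
  truncated below 0.97·τ_g (personal means below 0.88·τ_g), MT pitch
  excursions are drawn above 0.42 rad, and Flexion cycles faster than τ_g
  receive shallow excursions below 0.30 rad, so the duration+pitch rule
  separates the classes in the noise-free limit. A fifth of participants
  are "fast shallow" Flexion risers — quick, knee-driven rises just below
  τ_g without the momentum lean — whose labels depend *only* on the pitch
  condition; their prevalence gives the pitch feature a discriminative load
  comparable to the published sensitivity analysis, where removing pitch
  cost 17 F1 points.
* **Reproducibility**: a single master seed spawns per-participant
  generators; identical configuration and seed give bitwise-identical
  signals.

What passing tests on this generator do **not** show: robustness to real
accelerometer morphology (asymmetric impulses, tremor, freezing-of-gait
artefacts), chair-height or placement variation, gyroscope bias drift
beyond per-cycle windowing, or annotation error in the reference method.

## Numerical and design notes

* Sampling-rate handling: dominant-frequency estimation needs ≥8 s of
  signal; readers reject recordings under 2 s.
* Annotated cycles are half-open `[start, end)`; adjacent repetitions may
  share a boundary instant.
* Degenerate inputs: flat or noise-only signals produce a degenerate
  spectrum (time guard disabled with a warning) and, via the amplitude
  floor, zero detections rather than noise-driven "cycles".
* The stopband check of the filter oracle evaluates the analytic
  Butterworth gain at the bilinear-prewarped frequency; the continuous-time
  formula `1/(1+(f/f_c)^4)` is accurate in-band but ~19 % off at 50 Hz with
  a 400 Hz rate, where the absolute residual (~2×10⁻⁴) is negligible.
* Gyroscope channels receive the identical low-pass filter as the
  accelerometer channels.
* Matching is greedy nearest-neighbour on start times; swapping the roles
  of detected and annotated sets leaves count accuracy unchanged.
* Problem sizes in the test suite — one 35-participant study for the
  end-to-end checks, 300–500 draws for distributional checks, 200
  replicates for mixed-model recovery, 1000 random instances for the
  greedy-vs-exhaustive oracle — keep the whole suite under a minute while
  holding Monte-Carlo error well below the asserted margins.

## Known limitations

* One accepted peak per repetition boundary is an interpretation; datasets
  annotated with separate sit-to-stand and stand-to-sit events need their
  events merged before comparison.
* The interior-minimum sub-phase split is this package's construction; no
  reference definition of the rise/sit boundary is implemented.
* The dominant-frequency guard assumes one repetition rate per trial. A
  trial that mixes a slow and a fast regime can lose fast cycles whose
  period falls below `γ ×` the dominant period; the relaxation `γ = 0.75`
  bounds but does not eliminate this (visible as occasional merged cycles
  in mixed-strategy synthetic trials).
* Strategies beyond the two-class MT/Flexion scheme are out of scope, as
  are fall-risk prediction and real-time (on-device) operation.
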