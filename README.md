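# chairstand

Cycle-level analysis of the 30-second chair sit-to-stand test (30-s CST)
from a single waist-mounted IMU (e.g. a smartphone worn at the lower back).

The 30-s CST counts how often a person can stand up from a chair and sit
back down in 30 seconds. The stopwatch score hides most of the clinically
interesting signal: how long each repetition takes, and *how* the person
rises — with a rapid forward trunk lean that converts momentum into vertical
rise (**Momentum Transfer, MT**), or with a prolonged trunk flexion before
extension (**Flexion**), typical of frailer movers. `chairstand` extracts
both from one 400-Hz accelerometer + gyroscope recording, and ships the
statistics needed to validate the device against a reference method such as
video annotation.

## Method

All six channels are low-passed with a zero-phase, second-order Butterworth
filter at 6 Hz. Detection operates on the orientation-robust acceleration
magnitude `a_mag(t) = sqrt(a_x² + a_y² + a_z²)` with two subject-adaptive
thresholds:

* amplitude: `th_amp = α · (max a_mag − min a_mag)`, default `α = 0.2`;
* timing: `th_time = γ / DF`, where `DF` is the dominant frequency of
  `a_mag` from a Welch periodogram in 0.1–2.5 Hz and `γ = 0.75` relaxes the
  guard so faster-than-average cycles survive.

A candidate peak at `t_k` is accepted iff its height above the trial minimum
reaches `th_amp` **and** `t_k − t_{k−1} ≥ th_time` against the previous
accepted peak. Consecutive accepted peaks delimit full cycles
(`T_i = t_{k+1} − t_k`), split into sit-to-stand and stand-to-sit phases at
the quiet valley between the two transition impulses. Per cycle, trunk
pitch is integrated from the mediolateral gyroscope axis over the cycle
window, and the rising strategy follows the rule

```
strategy_i = MT       if T_i < τ_g  and  Δθ_i > θ_thresh
             Flexion  otherwise
```

with age-adjusted `τ_g` (1.2 s young / 1.6 s older / 2.0 s Parkinson's) and
`θ_thresh = 0.35 rad`. The agreement module provides Pearson/Spearman,
paired *t*, Bland–Altman bias and limits of agreement with CIs, ICC(2,1)
and ICC(3,1), macro F1 for strategy labels, and a random-intercept linear
mixed model `d_ij = β₀ + u_i + ε_ij` for per-cycle method differences
nested in participants, with nesting-aware limits of agreement.

A seeded simulator (`chairstand.simulate`) generates full virtual studies —
35 participants (10 young / 20 older / 5 Parkinson's), 30-s trials at
400 Hz with gravity, mounting tilt, sensor noise, seat-impact echo bursts
and strategy-dependent pitch waveforms — with exact ground truth, so every
stage is testable without recorded data.

## Worked example

```python
from chairstand import SimConfig, generate_cohort, analyze_trial, validate_cohort

cohort = generate_cohort(SimConfig(seed=1))           # 35 virtual participants
results = [analyze_trial(trial) for trial, _ in cohort]
truth = {trial.trial_id: gt.annotations for trial, gt in cohort}
val = validate_cohort(results, truth)
print(f"count accuracy {val.count_accuracy:.3f}")
print(f"timing MAE     {1e3 * val.timing_mae:.1f} ms")
print(f"macro F1       {val.macro_f1:.3f}")
print(f"ICC(2,1)       {val.participant_agreement.icc_2_1:.4f}")
```

prints

```
count accuracy 0.999
timing MAE     3.6 ms
macro F1       0.998
ICC(2,1)       0.9998
```

i.e. on this synthetic study the detector recovers 721 of 722 annotated
cycles, matched cycle durations err by under 4 ms on average, strategy
labels almost always agree with ground truth, and participant-level mean
cycle times from the two "methods" (device pipeline vs ground-truth
annotation) are statistically indistinguishable.

The same pipeline is available from the shell:

```bash
chairstand simulate --out data/ --seed 1
chairstand analyze  --input data/ --manifest data/manifest.json --out reports/
chairstand validate --reports reports/ --annotations data/annotations.csv --out validation.json
chairstand ablate   --data data/ --out ablation.json   # sensitivity grid
```

The `ablate` grid re-runs everything without the dominant-frequency guard,
without trunk pitch, without both, and at `α ∈ {0.1, 0.4}`: dropping the
frequency guard collapses count accuracy (~0.75) and inflates timing error
(~350 ms) because within-transition echo peaks are double-counted; dropping
pitch leaves detection untouched but degrades macro F1 (~0.85); removing
both is worst; the α extremes barely move any metric.

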