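"""Synthetic waist-IMU chair-stand trials with exact ground truth.

The generator emulates the statistical structure the detection and
classification stages assume, so every stage is testable without recorded
data:

* cohort composition 10 young / 20 older / 5 Parkinson's participants, 30-s
  trials sampled at 400 Hz;
* per-cohort, per-strategy full-cycle durations built from published
  descriptive means ± SDs, decomposed into a between-participant speed factor
  and small within-trial jitter (a trial's cycles are far more alike than the
  cohort-pooled SD suggests);
* trials are dominantly strategy-pure — the per-strategy repetition counts of
  the descriptive table each fill an entire 30-s trial — with an occasional
  single mid-trial regime switch (fatigue-style), so mixed trials exist but
  interleaved strategies do not;
* vertical acceleration is gravity plus a raised-cosine burst at every
  repetition boundary, a shallow quiet-valley dip at each rise/sit apex and,
  for most cycles, a smaller "seat-impact echo" bump shortly after the
  boundary — the realistic within-transition false positive that the
  dominant-frequency guard exists to reject;
* mediolateral angular velocity is a biphasic half-sine pair whose forward
  lobe integrates exactly to the requested pitch excursion and whose net
  integral over the closed cycle is ~0;
* a fixed mounting-tilt rotation and additive white Gaussian noise complete
  the signal model.

All randomness flows from a single master seed via ``numpy`` seed sequences.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from .io import FLEXION, MT, AnnotationSet, ImuTrial
from .strategy import DEFAULT_TAU_G

#: hard floor on physically plausible cycle duration (s)
MIN_CYCLE_DURATION = 0.4
#: quiet-valley dip depth at the rise/sit apex (m/s²)
APEX_DIP = 0.4
#: within-trial coefficient of variation of cycle duration
WITHIN_TRIAL_CV = 0.08
#: between-participant speed-factor SD (multiplicative, both strategies)
SPEED_FACTOR_SD = 0.15
#: Flexion cycles are 52-81 % slower than MT within a cohort
FLEXION_SLOWDOWN = (1.52, 1.81)
#: fraction of tau_g used to truncate MT durations so the time rule separates
MT_TAU_MARGIN_CYCLE = 0.97
MT_TAU_MARGIN_MEAN = 0.88
#: pitch excursion of fast (T < tau_g) Flexion cycles: shallow lean
FAST_FLEXION_PITCH = (0.22, 0.06, 0.05, 0.30)  # mean, sd, lo, hi (rad)
#: share of participants whose Flexion style is "fast but shallow" — quick
#: knee-driven rises without the momentum lean; their cycle times sit just
#: below tau_g so only the pitch condition separates them from MT
P_FAST_SHALLOW = 0.22
FAST_SHALLOW_DURATION = (0.80, 0.92)  # × tau_g


@dataclass(frozen=True)
class StrategyParams:
    """Per-strategy generative parameters of one cohort."""

    duration_mean: float  # s, full cycle
    duration_sd: float  # s, cohort-pooled
    rise_fraction: float  # rise time / full-cycle time
    burst_amp: tuple[float, float]  # m/s² above gravity, (lo, hi)
    pitch_mean: float  # rad
    pitch_sd: float
    pitch_lo: float
    pitch_hi: float


@dataclass(frozen=True)
class CohortProfile:
    """Population-level generative description of one cohort."""

    cohort: str
    mt: StrategyParams
    flexion: StrategyParams
    p_mt: float  # probability that MT is a participant's dominant strategy
    p_switch: float = 0.2  # probability of one mid-trial regime switch
    tau_g: float = 1.6

    def params(self, strategy: str) -> StrategyParams:
        return self.mt if strategy == MT else self.flexion


def _sp(mean, sd, rise, amp, pitch_mean, pitch_sd, lo, hi) -> StrategyParams:
    return StrategyParams(duration_mean=mean, duration_sd=sd, rise_fraction=rise,
                          burst_amp=amp, pitch_mean=pitch_mean, pitch_sd=pitch_sd,
                          pitch_lo=lo, pitch_hi=hi)


#: defaults drawn from the published per-cohort descriptive table; pitch
#: parameters are calibrated so the duration+pitch rule separates the classes
#: in the noise-free limit (MT lean well above 0.35 rad, fast Flexion below).
COHORT_PROFILES: dict[str, CohortProfile] = {
    "young": CohortProfile(
        cohort="young",
        mt=_sp(1.06, 0.20, 0.516, (8.0, 13.0), 0.55, 0.10, 0.42, 0.90),
        flexion=_sp(1.79, 0.20, 0.513, (6.0, 10.0), 0.50, 0.12, 0.10, 0.90),
        p_mt=0.85, tau_g=DEFAULT_TAU_G["young"]),
    "older": CohortProfile(
        cohort="older",
        mt=_sp(1.45, 0.40, 0.509, (7.0, 12.0), 0.55, 0.10, 0.42, 0.90),
        flexion=_sp(2.63, 0.80, 0.513, (6.0, 10.0), 0.50, 0.12, 0.10, 0.90),
        p_mt=0.70, tau_g=DEFAULT_TAU_G["older"]),
    "pd": CohortProfile(
        cohort="pd",
        mt=_sp(1.85, 0.30, 0.514, (4.0, 8.0), 0.55, 0.10, 0.42, 0.90),
        flexion=_sp(2.81, 0.60, 0.505, (3.5, 6.0), 0.50, 0.12, 0.10, 0.90),
        p_mt=0.25, tau_g=DEFAULT_TAU_G["pd"]),
}


@dataclass(frozen=True)
class SimConfig:
    """Study-level simulation settings."""

    n_young: int = 10
    n_older: int = 20
    n_pd: int = 5
    trial_len: float = 30.0  # s
    fs: float = 400.0  # Hz
    noise_sd_acc: float = 0.4  # m/s², raw white noise per axis
    noise_sd_gyr: float = 0.03  # rad/s
    gravity: float = 9.81  # m/s²
    tilt: float = 0.05  # rad, fixed mounting misalignment (roll)
    p_echo: float = 0.5  # seat-impact echo probability per eligible cycle
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs <= 0 or self.trial_len <= 0:
            raise ValueError("fs and trial_len must be positive")
        if self.noise_sd_acc < 0 or self.noise_sd_gyr < 0:
            raise ValueError("noise SDs must be non-negative")

    @property
    def cohort_sizes(self) -> dict[str, int]:
        return {"young": self.n_young, "older": self.n_older, "pd": self.n_pd}


@dataclass(frozen=True)
class CyclePlan:
    """Ground-truth construction parameters of one cycle."""

    strategy: str
    duration: float  # s
    rise_fraction: float
    pitch_excursion: float  # rad


@dataclass
class GroundTruth:
    """Everything the generator knows about an emitted trial."""

    annotations: AnnotationSet
    plans: list[CyclePlan]

    @property
    def n_cycles(self) -> int:
        return len(self.plans)

    @property
    def durations(self) -> np.ndarray:
        return np.array([p.duration for p in self.plans])

    @property
    def labels(self) -> list[str]:
        return [p.strategy for p in self.plans]


def _trunc_normal(rng: np.random.Generator, mean: float, sd: float,
                  lo: float, hi: float = np.inf) -> float:
    """Rejection-sampled truncated normal (bounds generous in practice)."""
    if sd <= 0:
        return float(np.clip(mean, lo, hi))
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return float(x)
    return float(np.clip(mean, lo, hi))


def personalize(profile: CohortProfile, rng: np.random.Generator) -> CohortProfile:
    """Draw one virtual participant from a cohort profile.

    A multiplicative speed factor shifts both strategy means together, the
    Flexion mean is tied to the MT mean through the published 52–81 %
    slowdown, and duration SDs shrink to the within-trial jitter.
    """
    speed = _trunc_normal(rng, 1.0, SPEED_FACTOR_SD, 0.7, 1.3)
    mt_mean = float(np.clip(speed * profile.mt.duration_mean,
                            1.5 * MIN_CYCLE_DURATION,
                            MT_TAU_MARGIN_MEAN * profile.tau_g))
    mt = dataclasses.replace(profile.mt, duration_mean=mt_mean,
                             duration_sd=WITHIN_TRIAL_CV * mt_mean)
    if rng.random() < P_FAST_SHALLOW:
        # fast shallow riser: Flexion timing just below tau_g, lean below
        # theta_thresh — only the pitch condition tells them from MT
        flex_mean = rng.uniform(*FAST_SHALLOW_DURATION) * profile.tau_g
        pm, ps, plo, phi = FAST_FLEXION_PITCH
        flexion = dataclasses.replace(
            profile.flexion, duration_mean=flex_mean,
            duration_sd=WITHIN_TRIAL_CV * flex_mean,
            pitch_mean=pm, pitch_sd=ps, pitch_lo=plo, pitch_hi=phi)
    else:
        flex_mean = mt_mean * rng.uniform(*FLEXION_SLOWDOWN)
        flexion = dataclasses.replace(profile.flexion, duration_mean=flex_mean,
                                      duration_sd=WITHIN_TRIAL_CV * flex_mean)
    return dataclasses.replace(profile, mt=mt, flexion=flexion)


def _draw_cycle(profile: CohortProfile, strategy: str,
                rng: np.random.Generator) -> CyclePlan:
    p = profile.params(strategy)
    if strategy == MT:
        duration = _trunc_normal(rng, p.duration_mean, p.duration_sd,
                                 MIN_CYCLE_DURATION,
                                 MT_TAU_MARGIN_CYCLE * profile.tau_g)
        pitch = _trunc_normal(rng, p.pitch_mean, p.pitch_sd, p.pitch_lo, p.pitch_hi)
    else:
        duration = _trunc_normal(rng, p.duration_mean, p.duration_sd,
                                 MIN_CYCLE_DURATION)
        if duration < profile.tau_g:
            # fast Flexion riser: shallow lean, otherwise the time+pitch rule
            # could not tell it from MT
            m, s, lo, hi = FAST_FLEXION_PITCH
            pitch = _trunc_normal(rng, m, s, lo, hi)
        else:
            pitch = _trunc_normal(rng, p.pitch_mean, p.pitch_sd, p.pitch_lo, p.pitch_hi)
    rise = float(np.clip(rng.normal(p.rise_fraction, 0.02), 0.35, 0.65))
    return CyclePlan(strategy=strategy, duration=duration,
                     rise_fraction=rise, pitch_excursion=pitch)


#: margins keeping the first/last burst clear of the filter edge exclusion
LEAD_IN = 0.75
TAIL = 0.6


def sample_cycle_sequence(profile: CohortProfile, trial_len: float,
                          rng: np.random.Generator,
                          dominant: str | None = None,
                          allow_switch: bool = True) -> list[CyclePlan]:
    """Sample the cycle plan of one trial.

    The dominant strategy (drawn with probability ``p_mt`` if not given)
    fills the trial; with probability ``p_switch`` the trial switches once to
    the other strategy at a uniformly placed instant. Cycles are appended
    until the next one would overrun the usable window.
    """
    if dominant is None:
        dominant = MT if rng.random() < profile.p_mt else FLEXION
    secondary = FLEXION if dominant == MT else MT
    switch_at = np.inf
    if allow_switch and rng.random() < profile.p_switch:
        switch_at = rng.uniform(0.3, 0.7) * trial_len
    usable_end = trial_len - TAIL
    plans: list[CyclePlan] = []
    t = LEAD_IN
    while True:
        strategy = dominant if t < switch_at else secondary
        plan = _draw_cycle(profile, strategy, rng)
        if t + plan.duration > usable_end:
            break
        plans.append(plan)
        t += plan.duration
    return plans


def _raised_cosine(t: np.ndarray, center: float, width: float) -> np.ndarray:
    """Unit-peak raised-cosine bump supported on ``[center ± width/2]``."""
    out = np.zeros_like(t)
    mask = np.abs(t - center) <= width / 2
    out[mask] = 0.5 * (1 + np.cos(2 * np.pi * (t[mask] - center) / width))
    return out


def _half_sine(t: np.ndarray, t0: float, duration: float, area: float) -> np.ndarray:
    """Half-sine lobe on ``[t0, t0+duration]`` integrating exactly to ``area``."""
    out = np.zeros_like(t)
    mask = (t >= t0) & (t <= t0 + duration)
    amp = np.pi * area / (2 * duration)
    out[mask] = amp * np.sin(np.pi * (t[mask] - t0) / duration)
    return out


def _tilt_matrix(tilt: float) -> np.ndarray:
    """Fixed mounting misalignment: roll about the antero-posterior axis."""
    c, s = np.cos(tilt), np.sin(tilt)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def synthesize_trial(sequence: list[CyclePlan], config: SimConfig, cohort: str,
                     rng: np.random.Generator,
                     trial_id: str = "sim") -> tuple[ImuTrial, GroundTruth]:
    """Render a cycle plan into a six-channel IMU trial plus ground truth."""
    profile = COHORT_PROFILES[cohort]
    n = int(round(config.trial_len * config.fs))
    t = np.arange(n) / config.fs

    durations = np.array([p.duration for p in sequence])
    boundaries = LEAD_IN + np.concatenate([[0.0], np.cumsum(durations)])
    if sequence and boundaries[-1] > config.trial_len - 1e-9:
        raise RuntimeError("cycle sequence overruns the trial window")

    acc_x = np.full(n, config.gravity)
    gyr_y = np.zeros(n)

    # boundary bursts (shared between adjacent cycles)
    amps = np.empty(len(boundaries))
    for j, b in enumerate(boundaries):
        adjacent = []
        if j > 0:
            adjacent.append(durations[j - 1])
        if j < len(durations):
            adjacent.append(durations[j])
        if not adjacent:
            break
        width = 0.3 * min(adjacent)
        amps[j] = rng.uniform(*profile.params(
            sequence[min(j, len(sequence) - 1)].strategy).burst_amp)
        acc_x += amps[j] * _raised_cosine(t, b, width)

    apex_times = np.empty(len(sequence))
    for i, plan in enumerate(sequence):
        start, end = boundaries[i], boundaries[i + 1]
        T = plan.duration
        apex = start + plan.rise_fraction * T
        apex_times[i] = apex
        # quiet valley anchoring the rise/sit split
        acc_x -= APEX_DIP * _raised_cosine(t, apex, 0.3 * T)
        # seat-impact echo shortly after the opening burst
        if T >= 1.1 and rng.random() < config.p_echo:
            echo_c = start + rng.uniform(0.28, 0.34) * T
            acc_x += rng.uniform(0.35, 0.5) * amps[i] * _raised_cosine(
                t, echo_c, 0.18 * T)
        # biphasic trunk pitch: forward lean then return
        fwd0 = start + 0.05 * T
        fwd_d = apex - fwd0
        back_d = (end - 0.05 * T) - apex
        gyr_y += _half_sine(t, fwd0, fwd_d, plan.pitch_excursion)
        gyr_y += _half_sine(t, apex, back_d, -plan.pitch_excursion)

    acc = np.column_stack([acc_x, np.zeros(n), np.zeros(n)])
    gyr = np.column_stack([np.zeros(n), gyr_y, np.zeros(n)])
    rot = _tilt_matrix(config.tilt)
    acc = acc @ rot.T
    gyr = gyr @ rot.T
    if config.noise_sd_acc > 0:
        acc = acc + rng.normal(0.0, config.noise_sd_acc, size=acc.shape)
    if config.noise_sd_gyr > 0:
        gyr = gyr + rng.normal(0.0, config.noise_sd_gyr, size=gyr.shape)

    trial = ImuTrial(time=t, acc=acc, gyr=gyr, fs_nominal=config.fs,
                     cohort=cohort, trial_id=trial_id, filtered=False)
    annotations = AnnotationSet(
        trial_id=trial_id, starts=boundaries[:-1], ends=boundaries[1:],
        labels=[p.strategy for p in sequence], apex_times=apex_times)
    return trial, GroundTruth(annotations=annotations, plans=list(sequence))


def generate_participant(cohort: str, config: SimConfig,
                         rng: np.random.Generator,
                         trial_id: str) -> tuple[ImuTrial, GroundTruth]:
    """One virtual participant: personalised profile, one 30-s trial."""
    profile = personalize(COHORT_PROFILES[cohort], rng)
    sequence = sample_cycle_sequence(profile, config.trial_len, rng)
    return synthesize_trial(sequence, config, cohort, rng, trial_id=trial_id)


def generate_cohort(config: SimConfig = SimConfig()
                    ) -> list[tuple[ImuTrial, GroundTruth]]:
    """The full virtual study: one trial per participant, master-seeded."""
    master = np.random.SeedSequence(config.seed)
    out: list[tuple[ImuTrial, GroundTruth]] = []
    children = iter(master.spawn(sum(config.cohort_sizes.values())))
    for cohort, size in config.cohort_sizes.items():
        for i in range(size):
            rng = np.random.default_rng(next(children))
            out.append(generate_participant(cohort, config, rng,
                                            trial_id=f"{cohort}{i:02d}"))
    return out
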