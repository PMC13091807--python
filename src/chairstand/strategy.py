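"""Trunk-pitch quantification and rule-based rising-strategy classification.

Trunk pitch within a cycle is obtained by trapezoidal integration of the
mediolateral-axis angular velocity over the window delimited by the detected
peaks; per-cycle windowing bounds gyroscope drift by the cycle duration.  A
cycle is labelled Momentum Transfer (MT) when it is both fast (full-cycle
time strictly below the age-adjusted threshold ``tau_g``) and shows a
meaningful forward pitch excursion (strictly above ``theta_thresh``);
otherwise it is a Flexion cycle.

Over a complete stand-and-return cycle the *net* pitch integral returns to
~0 by construction, so the default summary is the peak-to-trough excursion;
the literal net measure is retained for fidelity experiments.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .detection import Cycle
from .io import COHORTS, FLEXION, MT, ImuTrial

#: age-adjusted full-cycle time thresholds (s)
DEFAULT_TAU_G = {"young": 1.2, "older": 1.6, "pd": 2.0}
#: pitch-excursion threshold, ~20 degrees (rad)
DEFAULT_THETA_THRESH = 0.35


@dataclass(frozen=True)
class StrategyConfig:
    """Tunables of the MT/Flexion rule.

    ``use_pitch=False`` treats the pitch condition as always satisfied
    (ablation: classification on cycle time alone).  ``pitch_sign`` flips the
    mediolateral axis for devices mounted the other way up.
    """

    tau_g: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_TAU_G))
    theta_thresh: float = DEFAULT_THETA_THRESH
    pitch_measure: str = "excursion"  # or "net"
    pitch_sign: float = 1.0
    use_pitch: bool = True

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.tau_g.values()):
            raise ValueError("all tau_g must be positive")
        if self.theta_thresh <= 0:
            raise ValueError("theta_thresh must be positive")
        if self.pitch_measure not in ("net", "excursion"):
            raise ValueError("pitch_measure must be 'net' or 'excursion'")
        if self.pitch_sign not in (1.0, -1.0, 1, -1):
            raise ValueError("pitch_sign must be +1 or -1")


@dataclass
class PitchProfile:
    """Cumulative trunk pitch over one cycle window (theta[0] = 0)."""

    time: np.ndarray
    theta: np.ndarray
    delta_theta: float
    measure: str = "excursion"


def integrate_pitch(trial: ImuTrial, cycle: Cycle,
                    config: StrategyConfig = StrategyConfig()) -> PitchProfile:
    """Integrate mediolateral angular velocity over ``[start_t, end_t]``."""
    if cycle.start_t < trial.time[0] - 1e-9 or cycle.end_t > trial.time[-1] + 1e-9:
        raise ValueError("cycle window lies outside the trial span")
    i0 = int(np.searchsorted(trial.time, cycle.start_t, side="left"))
    i1 = int(np.searchsorted(trial.time, cycle.end_t, side="right"))
    t = trial.time[i0:i1]
    omega = config.pitch_sign * trial.gyr_y[i0:i1]
    if t.size < 2:
        raise ValueError("cycle window spans fewer than 2 samples")
    theta = cumulative_trapezoid(omega, t, initial=0.0)
    if config.pitch_measure == "net":
        delta = float(theta[-1] - theta[0])
    else:
        delta = float(theta.max() - theta.min())
    return PitchProfile(time=t, theta=theta, delta_theta=delta,
                        measure=config.pitch_measure)


def classify_cycle(cycle: Cycle, pitch: PitchProfile, cohort: str,
                   config: StrategyConfig = StrategyConfig()) -> str:
    """Apply the MT/Flexion rule (strict inequalities on both conditions)."""
    if cohort not in COHORTS:
        raise ValueError(f"unknown cohort {cohort!r}")
    fast = cycle.T < config.tau_g[cohort]
    leaning = (not config.use_pitch) or pitch.delta_theta > config.theta_thresh
    return MT if (fast and leaning) else FLEXION


def classify_trial(result, trial: ImuTrial,
                   config: StrategyConfig = StrategyConfig()):
    """Label every detected cycle of a trial in place (and return it).

    Labels may differ across cycles within one trial — participants do switch
    strategy mid-test.
    """
    for cycle in result.cycles:
        pitch = integrate_pitch(trial, cycle, config)
        cycle.delta_theta = pitch.delta_theta
        cycle.strategy = classify_cycle(cycle, pitch, trial.cohort, config)
    return result
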