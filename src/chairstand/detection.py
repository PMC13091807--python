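"""Subject-adaptive detection of chair sit-to-stand cycles.

The detector works on the low-passed acceleration magnitude of a trial and
adapts two thresholds to each recording:

* an amplitude threshold ``th_amp = alpha * (max - min)`` of the magnitude
  trace, scaling the acceptance rule to the participant's own movement range;
* a time threshold ``th_time = gamma / DF`` derived from the dominant
  frequency (Welch PSD argmax in a physiological band), which rejects
  candidate peaks arriving faster than the participant's repetition rate —
  typically secondary impulses inside a single transition.

Accepted peaks mark repetition boundaries; consecutive peaks delimit one full
stand-and-return cycle of duration ``T_i``, which is split into sit-to-stand
and stand-to-sit phases at the quiet valley (interior magnitude minimum).
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .errors import DataError, DegenerateSpectrumError
from .io import ImuTrial, resample_uniform, JITTER_TOLERANCE
from .preprocess import FilterSpec, MagnitudeSeries, lowpass_zero_phase, magnitude

log = logging.getLogger(__name__)

#: minimum signal length for Welch dominant-frequency estimation (seconds)
MIN_DF_DURATION = 8.0


@dataclass(frozen=True)
class DetectionConfig:
    """Tunable parameters of the cycle detector.

    ``alpha`` scales the adaptive amplitude threshold (smaller is more
    permissive).  ``gamma`` relaxes the dominant-frequency time guard so
    faster-than-average but valid cycles survive; ``gamma=1`` applies the
    strict reciprocal of the dominant frequency.  ``min_amplitude`` is an
    absolute floor (m/s²) on the amplitude threshold so that a trial
    containing no movement at all — where the adaptive range collapses to the
    sensor noise band — yields no detections.
    """

    alpha: float = 0.2
    df_band: tuple[float, float] = (0.1, 2.5)
    gamma: float = 0.75
    use_df_guard: bool = True
    baseline_correction: str = "min_offset"  # or "none"
    edge_exclusion: float = 0.25  # s
    min_amplitude: float = 1.0  # m/s²

    def __post_init__(self) -> None:
        if not 0 < self.alpha:
            raise ValueError("alpha must be positive")
        if not self.df_band[0] < self.df_band[1]:
            raise ValueError("df_band must be an increasing interval")
        if not 0 < self.gamma <= 1:
            raise ValueError("gamma must lie in (0, 1]")
        if self.baseline_correction not in ("min_offset", "none"):
            raise ValueError("baseline_correction must be 'min_offset' or 'none'")


@dataclass
class DetectionState:
    """Per-trial adaptive quantities, logged for auditability."""

    th_amp: float
    th_time: float
    df: float
    signal_min: float
    signal_max: float


@dataclass(frozen=True)
class Peak:
    index: int
    t: float
    amplitude: float


@dataclass
class Cycle:
    """One detected stand-and-return repetition."""

    start_t: float
    end_t: float
    apex_t: float | None = None
    rise_time: float | None = None
    sit_time: float | None = None
    delta_theta: float | None = None
    strategy: str | None = None
    degenerate_split: bool = False

    @property
    def T(self) -> float:
        """Full-cycle duration (s)."""
        return self.end_t - self.start_t


def estimate_dominant_frequency(mag: MagnitudeSeries, fs: float | None = None,
                                band: tuple[float, float] = (0.1, 2.5)) -> float:
    """Argmax of the Welch PSD of ``a_mag`` restricted to ``band`` (Hz).

    Welch settings: Hann window, segments of min(8 s, full length), 50 %
    overlap, mean detrend. Raises :class:`DegenerateSpectrumError` when no
    band power stands out (peak below 3x the band's median power).

    The lower edge of the search band is clipped to the spectral resolution
    limit of two full periods per Welch segment: a "peak" slower than that is
    an artefact of windowing, not a repetition rate.
    """
    fs = fs or mag.fs
    if mag.duration < MIN_DF_DURATION:
        raise DataError(f"need >= {MIN_DF_DURATION:.0f} s of signal for "
                        f"dominant-frequency estimation, got {mag.duration:.1f} s")
    nperseg = int(min(round(MIN_DF_DURATION * fs), mag.a_mag.size))
    freqs, psd = sps.welch(mag.a_mag, fs=fs, window="hann", nperseg=nperseg,
                           noverlap=nperseg // 2, detrend="constant")
    resolution_floor = 2.0 * fs / nperseg
    in_band = (freqs >= max(band[0], resolution_floor)) & (freqs <= band[1])
    if not in_band.any():
        raise DataError("dominant-frequency band contains no PSD bins")
    band_psd = psd[in_band]
    peak = float(band_psd.max())
    if not peak > 3.0 * float(np.median(band_psd)):
        raise DegenerateSpectrumError("no dominant spectral peak in band "
                                      f"[{band[0]}, {band[1]}] Hz")
    return float(freqs[in_band][np.argmax(band_psd)])


def compute_amplitude_threshold(mag: MagnitudeSeries, alpha: float) -> float:
    """Adaptive amplitude threshold ``alpha * (max - min)`` of the trace."""
    return alpha * float(mag.a_mag.max() - mag.a_mag.min())


def compute_time_threshold(df: float, gamma: float = 1.0) -> float:
    """Minimum inter-peak interval ``gamma / DF`` (s); ``gamma=1`` is strict."""
    if df <= 0:
        raise ValueError("dominant frequency must be positive")
    return gamma / df


def find_candidate_peaks(mag: MagnitudeSeries,
                         config: DetectionConfig = DetectionConfig()) -> list[Peak]:
    """Strict local maxima outside the edge-exclusion zones, time-ordered.

    Plateau maxima contribute their centre sample.
    """
    idx, _ = sps.find_peaks(mag.a_mag, plateau_size=1)
    t0 = mag.time[0] + config.edge_exclusion
    t1 = mag.time[-1] - config.edge_exclusion
    return [Peak(index=int(i), t=float(mag.time[i]), amplitude=float(mag.a_mag[i]))
            for i in idx if t0 <= mag.time[i] <= t1]


def accept_peaks(candidates: list[Peak], state: DetectionState,
                 config: DetectionConfig = DetectionConfig()) -> list[Peak]:
    """Greedy time-ordered acceptance of candidate peaks.

    A candidate is accepted iff its height above the baseline reaches
    ``th_amp`` (inclusive) and it arrives at least ``th_time`` after the last
    *accepted* peak; a rejected candidate does not reset the timing clock.
    With ``use_df_guard=False`` the timing condition is dropped entirely.
    """
    baseline = state.signal_min if config.baseline_correction == "min_offset" else 0.0
    accepted: list[Peak] = []
    for cand in candidates:
        if cand.amplitude - baseline < state.th_amp:
            continue
        if config.use_df_guard and accepted and cand.t - accepted[-1].t < state.th_time:
            continue
        accepted.append(cand)
    return accepted


def segment_cycles(peaks: list[Peak]) -> list[Cycle]:
    """n accepted peaks delimit n-1 full cycles; a trailing incomplete
    repetition contributes none."""
    return [Cycle(start_t=a.t, end_t=b.t) for a, b in zip(peaks[:-1], peaks[1:])]


def split_subphases(cycle: Cycle, mag: MagnitudeSeries) -> Cycle:
    """Split a cycle at the quiet valley between the stand and sit impulses.

    The apex is the global minimum of ``a_mag`` strictly inside the cycle;
    rise time runs start→apex, sit time apex→end. A monotone segment (no
    interior valley) is flagged and halved with a warning.
    """
    i0 = int(np.searchsorted(mag.time, cycle.start_t, side="left"))
    i1 = int(np.searchsorted(mag.time, cycle.end_t, side="right")) - 1
    interior = mag.a_mag[i0 + 1:i1]
    monotone = interior.size < 1 or bool(
        np.all(np.diff(mag.a_mag[i0:i1 + 1]) >= 0)
        or np.all(np.diff(mag.a_mag[i0:i1 + 1]) <= 0))
    if monotone:
        log.warning("cycle [%0.2f, %0.2f] has no interior valley; halving",
                    cycle.start_t, cycle.end_t)
        apex_t = cycle.start_t + cycle.T / 2
        half = cycle.T / 2
        return Cycle(start_t=cycle.start_t, end_t=cycle.end_t, apex_t=apex_t,
                     rise_time=half, sit_time=half, degenerate_split=True,
                     delta_theta=cycle.delta_theta, strategy=cycle.strategy)
    apex_idx = i0 + 1 + int(np.argmin(interior))
    apex_t = float(mag.time[apex_idx])
    return Cycle(start_t=cycle.start_t, end_t=cycle.end_t, apex_t=apex_t,
                 rise_time=apex_t - cycle.start_t, sit_time=cycle.end_t - apex_t,
                 delta_theta=cycle.delta_theta, strategy=cycle.strategy)


def _audit(accepted: list[Peak], state: DetectionState,
           config: DetectionConfig) -> None:
    """Post-hoc self-check that every accepted peak satisfies the rule."""
    baseline = state.signal_min if config.baseline_correction == "min_offset" else 0.0
    for prev, cur in zip([None] + accepted[:-1], accepted):
        assert cur.amplitude - baseline >= state.th_amp - 1e-12
        if config.use_df_guard and prev is not None:
            assert cur.t - prev.t >= state.th_time - 1e-12


def detect_trial(trial: ImuTrial, config: DetectionConfig = DetectionConfig(),
                 filter_spec: FilterSpec = FilterSpec()):
    """Run the full detection chain on one trial.

    Steps: (resample if jittery) → zero-phase low-pass → magnitude → dominant
    frequency → adaptive thresholds → candidate peaks → greedy acceptance →
    cycle segmentation → sub-phase split.  A degenerate spectrum downgrades
    the dominant-frequency guard with a warning instead of failing the trial.
    """
    from .metrics import TrialResult

    if trial.timestamp_jitter > JITTER_TOLERANCE:
        log.warning("trial %r: timestamp jitter %.1f%% > %.0f%%; resampling to "
                    "%.0f Hz", trial.trial_id, 100 * trial.timestamp_jitter,
                    100 * JITTER_TOLERANCE, trial.fs_nominal)
        trial = resample_uniform(trial, trial.fs_nominal)
    if not trial.filtered:
        trial = lowpass_zero_phase(trial, filter_spec)
    mag = magnitude(trial)

    use_guard = config.use_df_guard
    try:
        df = estimate_dominant_frequency(mag, band=config.df_band)
        th_time = compute_time_threshold(df, config.gamma)
    except DegenerateSpectrumError:
        warnings.warn(f"trial {trial.trial_id!r}: degenerate spectrum, "
                      "disabling dominant-frequency guard", stacklevel=2)
        df, th_time, use_guard = float("nan"), 0.0, False

    th_amp = max(compute_amplitude_threshold(mag, config.alpha),
                 config.min_amplitude)
    state = DetectionState(th_amp=th_amp, th_time=th_time, df=df,
                           signal_min=float(mag.a_mag.min()),
                           signal_max=float(mag.a_mag.max()))
    run_config = DetectionConfig(**{**config.__dict__, "use_df_guard": use_guard})
    candidates = find_candidate_peaks(mag, run_config)
    accepted = accept_peaks(candidates, state, run_config)
    _audit(accepted, state, run_config)
    cycles = [split_subphases(c, mag) for c in segment_cycles(accepted)]
    log.info("trial %r: DF=%.3f Hz th_amp=%.2f m/s² th_time=%.2f s -> %d cycles",
             trial.trial_id, df, th_amp, th_time, len(cycles))
    return TrialResult(trial_id=trial.trial_id, cohort=trial.cohort,
                       detection_state=state, cycles=cycles)
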