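"""Cycle-level summary metrics and detection-vs-annotation comparison.

``summarize_trial`` produces the per-strategy descriptive table (mean ± SD of
phase and full-cycle times, counts, kinematic ranges). ``match_cycles`` pairs
detected and annotated cycles one-to-one by nearest start time, from which
count accuracy and timing MAE follow; both misses and spurious detections
penalise the accuracy because it is normalised by the larger of the two
counts.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .detection import Cycle, DetectionState
from .errors import DataError
from .io import AnnotationSet, ImuTrial, STRATEGIES


@dataclass
class TrialResult:
    """Everything the pipeline derived from one trial."""

    trial_id: str
    cohort: str
    detection_state: DetectionState | None
    cycles: list[Cycle] = field(default_factory=list)

    @property
    def counts(self) -> dict[str, int]:
        labels = [c.strategy for c in self.cycles if c.strategy is not None]
        return {s: labels.count(s) for s in STRATEGIES}

    @property
    def n_cycles(self) -> int:
        return len(self.cycles)

    @property
    def durations(self) -> np.ndarray:
        return np.array([c.T for c in self.cycles])


@dataclass
class StrategyStats:
    """Descriptives for the cycles of one strategy within a trial."""

    n: int
    t_mean: float
    t_sd: float | None
    rise_mean: float | None
    rise_sd: float | None
    sit_mean: float | None
    sit_sd: float | None
    acc_vertical_range: tuple[float, float] | None = None
    gyr_mediolateral_range: tuple[float, float] | None = None


@dataclass
class TrialSummary:
    trial_id: str
    cohort: str
    per_strategy: dict[str, StrategyStats]

    @property
    def total_cycles(self) -> int:
        return sum(s.n for s in self.per_strategy.values())


def _mean_sd(values: list[float]) -> tuple[float | None, float | None]:
    vals = [v for v in values if v is not None]
    if not vals:
        return None, None
    mean = float(np.mean(vals))
    sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else None
    return mean, sd


def summarize_trial(result: TrialResult, trial: ImuTrial | None = None) -> TrialSummary:
    """Per-strategy aggregates; strategies with no cycles are absent.

    Sample (n-1) standard deviations; SD is ``None`` for singleton groups.
    Kinematic ranges require the source ``trial``.
    """
    per: dict[str, StrategyStats] = {}
    for strat in STRATEGIES:
        cycles = [c for c in result.cycles if c.strategy == strat]
        if not cycles:
            continue
        t_mean, t_sd = _mean_sd([c.T for c in cycles])
        rise_mean, rise_sd = _mean_sd([c.rise_time for c in cycles])
        sit_mean, sit_sd = _mean_sd([c.sit_time for c in cycles])
        acc_range = gyr_range = None
        if trial is not None:
            masks = [(trial.time >= c.start_t) & (trial.time <= c.end_t)
                     for c in cycles]
            member = np.logical_or.reduce(masks)
            if member.any():
                acc_range = (float(trial.acc_x[member].min()),
                             float(trial.acc_x[member].max()))
                gyr_range = (float(trial.gyr_y[member].min()),
                             float(trial.gyr_y[member].max()))
        per[strat] = StrategyStats(n=len(cycles), t_mean=t_mean, t_sd=t_sd,
                                   rise_mean=rise_mean, rise_sd=rise_sd,
                                   sit_mean=sit_mean, sit_sd=sit_sd,
                                   acc_vertical_range=acc_range,
                                   gyr_mediolateral_range=gyr_range)
    return TrialSummary(trial_id=result.trial_id, cohort=result.cohort,
                        per_strategy=per)


@dataclass
class MatchResult:
    """One-to-one pairing of detected and annotated cycles for one trial."""

    pairs: list[tuple[int, int]]  # (detected index, annotated index)
    n_detected: int
    n_annotated: int
    count_accuracy: float
    timing_mae: float | None  # s, over matched pairs
    start_offsets: np.ndarray  # s, detected - annotated start per pair
    duration_errors: np.ndarray  # s, |detected T - annotated T| per pair

    @property
    def n_matched(self) -> int:
        return len(self.pairs)

    @property
    def unmatched_detected(self) -> int:
        return self.n_detected - self.n_matched

    @property
    def unmatched_annotated(self) -> int:
        return self.n_annotated - self.n_matched


def match_cycles(detected: list[Cycle], truth: AnnotationSet,
                 tol: float | None = None) -> MatchResult:
    """Greedy nearest-neighbour matching on cycle start times.

    Candidate pairs within ``tol`` (default: half the median annotated cycle
    duration) are taken in order of increasing start-time distance, each
    detected and annotated cycle at most once.
    """
    if truth.n == 0:
        raise ValueError("empty annotation set")
    if tol is None:
        tol = 0.5 * float(np.median(truth.durations))
    det_starts = np.array([c.start_t for c in detected])
    det_T = np.array([c.T for c in detected])

    candidates = sorted(
        ((abs(det_starts[i] - truth.starts[j]), i, j)
         for i in range(len(detected)) for j in range(truth.n)
         if abs(det_starts[i] - truth.starts[j]) <= tol),
        key=lambda x: (x[0], x[1], x[2]))
    used_det: set[int] = set()
    used_ann: set[int] = set()
    pairs: list[tuple[int, int]] = []
    for _, i, j in candidates:
        if i in used_det or j in used_ann:
            continue
        pairs.append((i, j))
        used_det.add(i)
        used_ann.add(j)
    pairs.sort()
    offsets = np.array([det_starts[i] - truth.starts[j] for i, j in pairs])
    errors = np.array([abs(det_T[i] - truth.durations[j]) for i, j in pairs])
    accuracy = len(pairs) / max(len(detected), truth.n)
    mae = float(errors.mean()) if len(pairs) else None
    return MatchResult(pairs=pairs, n_detected=len(detected), n_annotated=truth.n,
                       count_accuracy=accuracy, timing_mae=mae,
                       start_offsets=offsets, duration_errors=errors)


def matched_labels(result: TrialResult, truth: AnnotationSet,
                   match: MatchResult) -> tuple[list[str], list[str]]:
    """(annotated, predicted) strategy labels over the matched pairs."""
    true_labels = [truth.labels[j] for _, j in match.pairs]
    pred_labels = [result.cycles[i].strategy for i, _ in match.pairs]
    return true_labels, pred_labels
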