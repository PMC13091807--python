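"""End-to-end composition: detect + classify one trial, validate a cohort."""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .agreement import (AgreementReport, LmmFit, PairedMeasurements,
                        agreement_report, fit_random_intercept_lmm, icc,
                        macro_f1)
from .detection import DetectionConfig, detect_trial
from .io import AnnotationSet, ImuTrial
from .metrics import MatchResult, TrialResult, match_cycles, matched_labels
from .preprocess import FilterSpec
from .strategy import StrategyConfig, classify_trial


def analyze_trial(trial: ImuTrial,
                  detection: DetectionConfig = DetectionConfig(),
                  strategy: StrategyConfig = StrategyConfig(),
                  filter_spec: FilterSpec = FilterSpec()) -> TrialResult:
    """Detect cycles and label every one with its rising strategy."""
    result = detect_trial(trial, detection, filter_spec)
    return classify_trial(result, trial, strategy)


@dataclass
class CohortValidation:
    """Pooled comparison of detected results against annotations."""

    count_accuracy: float
    timing_mae: float | None  # s, pooled over matched cycles
    macro_f1: float | None
    n_annotated: int
    n_detected: int
    n_matched: int
    per_trial: dict[str, MatchResult] = field(default_factory=dict)
    participant_agreement: AgreementReport | None = None
    icc_3_1_counts: float | None = None
    icc_3_1_time: float | None = None
    lmm: LmmFit | None = None


def validate_cohort(results: list[TrialResult],
                    annotations: dict[str, AnnotationSet],
                    tol: float | None = None,
                    fit_lmm: bool = True) -> CohortValidation:
    """Match every trial, pool accuracy/MAE/F1, and run the agreement stats.

    Participant-level agreement (correlations, paired t, Bland–Altman, ICC)
    compares each trial's mean detected cycle time with its mean annotated
    cycle time; the mixed model uses the per-matched-cycle differences nested
    in participants.
    """
    matches: dict[str, MatchResult] = {}
    truth_labels: list[str] = []
    pred_labels: list[str] = []
    cycle_diffs: list[float] = []
    cycle_units: list[str] = []
    mean_det: list[float] = []
    mean_ann: list[float] = []
    count_det: list[float] = []
    count_ann: list[float] = []
    unit_ids: list[str] = []
    errors: list[np.ndarray] = []

    for result in results:
        truth = annotations[result.trial_id]
        match = match_cycles(result.cycles, truth, tol=tol)
        matches[result.trial_id] = match
        tl, pl = matched_labels(result, truth, match)
        truth_labels += tl
        pred_labels += pl
        errors.append(match.duration_errors)
        for i, j in match.pairs:
            cycle_diffs.append(result.cycles[i].T - float(truth.durations[j]))
            cycle_units.append(result.trial_id)
        if result.cycles:
            mean_det.append(float(np.mean([c.T for c in result.cycles])))
            mean_ann.append(float(truth.durations.mean()))
            unit_ids.append(result.trial_id)
            count_det.append(result.n_cycles)
            count_ann.append(truth.n)

    n_ann = sum(m.n_annotated for m in matches.values())
    n_det = sum(m.n_detected for m in matches.values())
    n_matched = sum(m.n_matched for m in matches.values())
    denom = sum(max(m.n_detected, m.n_annotated) for m in matches.values())
    accuracy = n_matched / denom if denom else 0.0
    all_errors = np.concatenate(errors) if errors else np.array([])
    mae = float(all_errors.mean()) if all_errors.size else None
    f1 = macro_f1(truth_labels, pred_labels) if truth_labels else None

    agreement = icc_counts = icc_time = lmm = None
    if len(unit_ids) >= 3:
        pairs = PairedMeasurements(unit_ids, np.array(mean_det), np.array(mean_ann))
        agreement = agreement_report(pairs)
        icc_counts = icc(np.column_stack([count_det, count_ann]), "3_1")
        icc_time = icc(np.column_stack([mean_det, mean_ann]), "3_1")
        if fit_lmm and len(set(cycle_units)) >= 3:
            lmm = fit_random_intercept_lmm(np.array(cycle_diffs), cycle_units)

    return CohortValidation(
        count_accuracy=accuracy, timing_mae=mae, macro_f1=f1,
        n_annotated=n_ann, n_detected=n_det, n_matched=n_matched,
        per_trial=matches, participant_agreement=agreement,
        icc_3_1_counts=icc_counts, icc_3_1_time=icc_time, lmm=lmm)


#: the ablation grid mirroring the sensitivity analysis
ABLATION_CONFIGS: dict[str, dict] = {
    "full": {},
    "no_df_guard": {"use_df_guard": False},
    "no_pitch": {"use_pitch": False},
    "neither": {"use_df_guard": False, "use_pitch": False},
    "alpha_0.1": {"alpha": 0.1},
    "alpha_0.4": {"alpha": 0.4},
}


def run_ablation(trials: list[ImuTrial], annotations: dict[str, AnnotationSet],
                 base_detection: DetectionConfig = DetectionConfig(),
                 base_strategy: StrategyConfig = StrategyConfig(),
                 configs: dict[str, dict] | None = None,
                 fit_lmm: bool = False) -> dict[str, CohortValidation]:
    """Re-run the pipeline under each ablation configuration."""
    import dataclasses

    out: dict[str, CohortValidation] = {}
    for name, overrides in (configs or ABLATION_CONFIGS).items():
        det_over = {k: v for k, v in overrides.items()
                    if k in {f.name for f in dataclasses.fields(DetectionConfig)}}
        strat_over = {k: v for k, v in overrides.items() if k not in det_over}
        det = dataclasses.replace(base_detection, **det_over)
        strat = dataclasses.replace(base_strategy, **strat_over)
        results = [analyze_trial(tr, det, strat) for tr in trials]
        out[name] = validate_cohort(results, annotations, fit_lmm=fit_lmm)
    return out
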