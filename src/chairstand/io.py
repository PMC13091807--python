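"""Reading, writing and normalisation of IMU recordings and annotations.

File conventions
----------------
IMU CSV       header ``time,acc_x,acc_y,acc_z,gyr_x,gyr_y,gyr_z``; seconds,
              m/s² and rad/s; x is vertical, y mediolateral, z antero-posterior.
Annotations   header ``trial_id,start_s,end_s,strategy`` (optional ``apex_s``);
              cycles are half-open ``[start, end)`` so adjacent repetitions may
              share a boundary instant.
Cycle report  JSON, one object per trial; round-trips losslessly through
              :func:`read_cycle_report`.
"""
from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DataError, FormatError

log = logging.getLogger(__name__)

COHORTS = ("young", "older", "pd")
IMU_COLUMNS = ("time", "acc_x", "acc_y", "acc_z", "gyr_x", "gyr_y", "gyr_z")

#: canonical rising-strategy labels
MT = "MT"
FLEXION = "Flexion"
STRATEGIES = (MT, FLEXION)

_STRATEGY_ALIASES = {"mt": MT, "momentum transfer": MT,
                     "flexion": FLEXION, "flex": FLEXION}

#: relative timestamp jitter above which analysis resamples to a uniform grid
JITTER_TOLERANCE = 0.05


def canonical_strategy(label: str) -> str:
    """Map a free-form strategy string onto ``"MT"`` or ``"Flexion"``."""
    try:
        return _STRATEGY_ALIASES[str(label).strip().lower()]
    except KeyError:
        raise FormatError(f"unknown rising-strategy label {label!r}") from None


@dataclass
class ImuTrial:
    """One six-channel inertial recording of a 30-s chair-stand trial.

    ``acc`` and ``gyr`` are ``(n, 3)`` arrays whose columns are the vertical,
    mediolateral and antero-posterior axes of the waist-mounted device.
    """

    time: np.ndarray
    acc: np.ndarray
    gyr: np.ndarray
    fs_nominal: float
    cohort: str
    trial_id: str = ""
    filtered: bool = False

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.acc = np.asarray(self.acc, dtype=float)
        self.gyr = np.asarray(self.gyr, dtype=float)
        n = self.time.shape[0]
        if n < 2:
            raise DataError("a trial needs at least 2 samples")
        if self.acc.shape != (n, 3) or self.gyr.shape != (n, 3):
            raise DataError("acc/gyr must be (n, 3) arrays matching time")
        if not (np.isfinite(self.time).all() and np.isfinite(self.acc).all()
                and np.isfinite(self.gyr).all()):
            raise DataError("non-finite values in trial channels")
        if np.any(np.diff(self.time) <= 0):
            raise DataError("time vector must be strictly increasing")
        if self.fs_nominal <= 0:
            raise DataError("fs_nominal must be positive")
        if self.cohort not in COHORTS:
            raise DataError(f"cohort must be one of {COHORTS}, got {self.cohort!r}")

    # -- channel views -------------------------------------------------
    @property
    def acc_x(self) -> np.ndarray:
        return self.acc[:, 0]

    @property
    def acc_y(self) -> np.ndarray:
        return self.acc[:, 1]

    @property
    def acc_z(self) -> np.ndarray:
        return self.acc[:, 2]

    @property
    def gyr_x(self) -> np.ndarray:
        return self.gyr[:, 0]

    @property
    def gyr_y(self) -> np.ndarray:
        return self.gyr[:, 1]

    @property
    def gyr_z(self) -> np.ndarray:
        return self.gyr[:, 2]

    @property
    def n(self) -> int:
        return self.time.shape[0]

    @property
    def duration(self) -> float:
        return float(self.time[-1] - self.time[0])

    @property
    def median_dt(self) -> float:
        return float(np.median(np.diff(self.time)))

    @property
    def timestamp_jitter(self) -> float:
        """Maximum relative deviation of sample spacing from the median."""
        dt = np.diff(self.time)
        med = np.median(dt)
        return float(np.max(np.abs(dt - med)) / med)

    def replace(self, **changes) -> "ImuTrial":
        return dataclasses.replace(self, **changes)


@dataclass
class AnnotationSet:
    """Ground-truth cycle boundaries and strategy labels for one trial."""

    trial_id: str
    starts: np.ndarray
    ends: np.ndarray
    labels: list[str]
    apex_times: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.starts = np.asarray(self.starts, dtype=float)
        self.ends = np.asarray(self.ends, dtype=float)
        if not (len(self.starts) == len(self.ends) == len(self.labels)):
            raise DataError("starts, ends and labels must have equal length")
        if np.any(self.ends <= self.starts):
            raise DataError("each annotated cycle needs start < end")
        order = np.argsort(self.starts, kind="stable")
        self.starts = self.starts[order]
        self.ends = self.ends[order]
        self.labels = [canonical_strategy(self.labels[i]) for i in order]
        if self.apex_times is not None:
            self.apex_times = np.asarray(self.apex_times, dtype=float)[order]
        # half-open cycles may share a boundary instant but not overlap
        if np.any(self.starts[1:] < self.ends[:-1] - 1e-9):
            raise DataError("annotated cycles overlap")

    @property
    def n(self) -> int:
        return len(self.labels)

    @property
    def durations(self) -> np.ndarray:
        return self.ends - self.starts


def read_imu_csv(path: str | Path, cohort: str, trial_id: str | None = None,
                 degrees: bool = False) -> ImuTrial:
    """Read a raw IMU CSV into an :class:`ImuTrial`.

    Rows containing NaN/Inf in any channel are dropped with a logged count.
    ``fs_nominal`` is inferred from the median sample spacing. ``degrees=True``
    converts gyroscope columns from deg/s to rad/s on read; units are never
    guessed silently.
    """
    path = Path(path)
    frame = pd.read_csv(path)
    for col in IMU_COLUMNS:
        if col not in frame.columns:
            raise FormatError(f"IMU CSV {path.name} is missing column {col!r}")
    data = frame.loc[:, list(IMU_COLUMNS)].to_numpy(dtype=float)
    good = np.isfinite(data).all(axis=1)
    n_bad = int((~good).sum())
    if n_bad:
        log.warning("%s: dropped %d row(s) with non-finite values", path.name, n_bad)
    data = data[good]
    if data.shape[0] < 2:
        raise DataError(f"{path.name}: fewer than 2 usable rows")
    time = data[:, 0]
    if np.any(np.diff(time) <= 0):
        raise DataError(f"{path.name}: time column is not strictly increasing")
    if time[-1] - time[0] < 2.0:
        raise DataError(f"{path.name}: under 2 s of usable data, too short for "
                        "dominant-frequency estimation")
    gyr = data[:, 4:7]
    if degrees:
        gyr = np.deg2rad(gyr)
    fs = 1.0 / float(np.median(np.diff(time)))
    return ImuTrial(time=time, acc=data[:, 1:4], gyr=gyr, fs_nominal=fs,
                    cohort=cohort, trial_id=trial_id or path.stem, filtered=False)


def write_imu_csv(trial: ImuTrial, path: str | Path) -> None:
    """Write a trial in the package's IMU CSV convention."""
    frame = pd.DataFrame({
        "time": trial.time,
        "acc_x": trial.acc_x, "acc_y": trial.acc_y, "acc_z": trial.acc_z,
        "gyr_x": trial.gyr_x, "gyr_y": trial.gyr_y, "gyr_z": trial.gyr_z,
    })
    frame.to_csv(path, index=False, float_format="%.9g")


def resample_uniform(trial: ImuTrial, fs_target: float) -> ImuTrial:
    """Linearly interpolate a trial onto a uniform grid at ``fs_target``.

    Identity (a copy) when the input is already uniform at the target rate
    within 1 ns jitter.
    """
    if fs_target <= 0:
        raise ValueError("fs_target must be positive")
    dt = np.diff(trial.time)
    if (abs(trial.median_dt - 1.0 / fs_target) < 1e-9
            and np.max(np.abs(dt - dt[0])) < 1e-9):
        return trial.replace()
    t0, t1 = trial.time[0], trial.time[-1]
    m = int(np.floor((t1 - t0) * fs_target)) + 1
    grid = t0 + np.arange(m) / fs_target
    acc = np.column_stack([np.interp(grid, trial.time, trial.acc[:, j]) for j in range(3)])
    gyr = np.column_stack([np.interp(grid, trial.time, trial.gyr[:, j]) for j in range(3)])
    return trial.replace(time=grid, acc=acc, gyr=gyr, fs_nominal=float(fs_target))


def _annotation_set_from_frame(trial_id: str, group: pd.DataFrame) -> AnnotationSet:
    apex = None
    if "apex_s" in group.columns and group["apex_s"].notna().all():
        apex = group["apex_s"].to_numpy(dtype=float)
    return AnnotationSet(
        trial_id=trial_id,
        starts=group["start_s"].to_numpy(dtype=float),
        ends=group["end_s"].to_numpy(dtype=float),
        labels=[canonical_strategy(s) for s in group["strategy"]],
        apex_times=apex,
    )


def read_all_annotations(path: str | Path) -> dict[str, AnnotationSet]:
    """Read an annotation CSV covering any number of trials."""
    path = Path(path)
    frame = pd.read_csv(path)
    for col in ("trial_id", "start_s", "end_s", "strategy"):
        if col not in frame.columns:
            raise FormatError(f"annotation CSV {path.name} is missing column {col!r}")
    return {str(tid): _annotation_set_from_frame(str(tid), group)
            for tid, group in frame.groupby("trial_id", sort=True)}


def read_annotations(path: str | Path, trial_id: str | None = None) -> AnnotationSet:
    """Read the annotations of a single trial (the only one, or ``trial_id``)."""
    table = read_all_annotations(path)
    if trial_id is not None:
        try:
            return table[trial_id]
        except KeyError:
            raise DataError(f"no annotations for trial {trial_id!r} in {path}") from None
    if len(table) != 1:
        raise DataError(f"{path} holds {len(table)} trials; pass trial_id")
    return next(iter(table.values()))


def write_annotations(annotations: "AnnotationSet | list[AnnotationSet]",
                      path: str | Path) -> None:
    if isinstance(annotations, AnnotationSet):
        annotations = [annotations]
    rows = []
    for ann in annotations:
        for i in range(ann.n):
            row = {"trial_id": ann.trial_id, "start_s": ann.starts[i],
                   "end_s": ann.ends[i], "strategy": ann.labels[i]}
            if ann.apex_times is not None:
                row["apex_s"] = ann.apex_times[i]
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.12g")


# -- cycle reports ------------------------------------------------------

def write_cycle_report(result, path: str | Path) -> None:
    """Serialise a :class:`~chairstand.metrics.TrialResult` as JSON."""
    state = result.detection_state
    payload = {
        "trial_id": result.trial_id,
        "cohort": result.cohort,
        "detection": None if state is None else {
            "df_hz": state.df, "th_amp": state.th_amp, "th_time": state.th_time,
            "signal_min": state.signal_min, "signal_max": state.signal_max,
        },
        "n_cycles": len(result.cycles),
        "counts": result.counts,
        "cycles": [{
            "start_t": c.start_t, "end_t": c.end_t, "apex_t": c.apex_t,
            "T": c.T, "rise_time": c.rise_time, "sit_time": c.sit_time,
            "delta_theta": c.delta_theta, "strategy": c.strategy,
            "degenerate_split": c.degenerate_split,
        } for c in result.cycles],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def read_cycle_report(path: str | Path):
    """Inverse of :func:`write_cycle_report`."""
    from .detection import Cycle, DetectionState
    from .metrics import TrialResult

    with open(path) as fh:
        payload = json.load(fh)
    det = payload.get("detection")
    state = None if det is None else DetectionState(
        th_amp=det["th_amp"], th_time=det["th_time"], df=det["df_hz"],
        signal_min=det["signal_min"], signal_max=det["signal_max"])
    cycles = [Cycle(start_t=c["start_t"], end_t=c["end_t"], apex_t=c["apex_t"],
                    rise_time=c["rise_time"], sit_time=c["sit_time"],
                    delta_theta=c["delta_theta"], strategy=c["strategy"],
                    degenerate_split=c.get("degenerate_split", False))
              for c in payload["cycles"]]
    return TrialResult(trial_id=payload["trial_id"], cohort=payload["cohort"],
                       detection_state=state, cycles=cycles)
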