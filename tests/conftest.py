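import numpy as np
import pytest

from chairstand import (DetectionConfig, ImuTrial, SimConfig, StrategyConfig,
                        generate_cohort)
from chairstand.pipeline import run_ablation

#: master seed of the virtual study used by the end-to-end tests
STUDY_SEED = 7


def make_trial(time, acc_x=None, acc_y=None, acc_z=None,
               gyr_x=None, gyr_y=None, gyr_z=None,
               cohort="older", fs=None, filtered=False, trial_id="test"):
    """Build an ImuTrial from whichever channels a test cares about."""
    time = np.asarray(time, dtype=float)
    n = time.size
    zeros = np.zeros(n)

    def ch(x):
        return zeros if x is None else np.asarray(x, dtype=float)

    acc = np.column_stack([ch(acc_x), ch(acc_y), ch(acc_z)])
    gyr = np.column_stack([ch(gyr_x), ch(gyr_y), ch(gyr_z)])
    if fs is None:
        fs = 1.0 / float(np.median(np.diff(time)))
    return ImuTrial(time=time, acc=acc, gyr=gyr, fs_nominal=fs,
                    cohort=cohort, trial_id=trial_id, filtered=filtered)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def sim_cohort():
    """The default 35-participant virtual study at a fixed seed."""
    return generate_cohort(SimConfig(seed=STUDY_SEED))


@pytest.fixture(scope="session")
def cohort_annotations(sim_cohort):
    return {trial.trial_id: truth.annotations for trial, truth in sim_cohort}


@pytest.fixture(scope="session")
def ablation_grid(sim_cohort, cohort_annotations):
    """Validation of the study under every ablation configuration."""
    trials = [trial for trial, _ in sim_cohort]
    return run_ablation(trials, cohort_annotations,
                        base_detection=DetectionConfig(),
                        base_strategy=StrategyConfig())
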