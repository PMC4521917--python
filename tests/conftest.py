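import numpy as np
import pytest

from swaysom.preprocess import UniformTrial
from swaysom.synthetic import (CohortConfig, DEFAULT_CONDITIONS,
                               FRONTAL_LANDMARKS, SubjectSpec, generate_cohort)


def make_frontal_trial(x_lower_back: np.ndarray, rate: float = 30.0,
                       shoulder_gain: float = 1.25,
                       shoulder_lead_frames: int = 0) -> UniformTrial:
    """Build a 9-landmark frontal trial whose ML motion follows a given
    lower-back signal (shoulders optionally lead by a frame offset)."""
    n = len(x_lower_back)
    positions = np.zeros((n, len(FRONTAL_LANDMARKS), 2))
    shoulder = shoulder_gain * np.roll(x_lower_back, -shoulder_lead_frames)
    for s, name in enumerate(FRONTAL_LANDMARKS):
        if "shoulder" in name or name in ("head", "neck"):
            positions[:, s, 0] = shoulder
        else:
            positions[:, s, 0] = x_lower_back
        positions[:, s, 1] = 1.0 + 0.1 * s
    return UniformTrial(trial_id="toy", subject_id="S", condition_id=1,
                        group="young", rate=rate, positions=positions,
                        segment_names=FRONTAL_LANDMARKS, axes=("x", "y"))


@pytest.fixture()
def sinusoid_trial():
    """12 full 0.5 Hz sway periods at 30 Hz, cosine-phased so cycle
    boundaries (outermost-left) fall at integer periods."""
    t = np.arange(0, 24.0, 1 / 30)
    x = -0.10 * np.cos(2 * np.pi * 0.5 * t)
    return make_frontal_trial(x)


@pytest.fixture(scope="session")
def default_subject():
    return SubjectSpec(subject_id="S1", group="young", stature_scale=1.0,
                       base_amplitude=0.10, base_frequency=0.5,
                       variability_level=0.05, seed=7)


@pytest.fixture(scope="session")
def neutral_condition():
    return DEFAULT_CONDITIONS[1]


@pytest.fixture(scope="session")
def small_cohort():
    """24-trial cohort (4 + 4 subjects, conditions 1/3/5, one corrupted
    trial per group) shared across modules."""
    config = CohortConfig(n_young=4, n_old=4, condition_ids=(1, 3, 5),
                          trials_per_condition=1, corrupted_young=1,
                          corrupted_old=1, seed=5)
    return generate_cohort(config)
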