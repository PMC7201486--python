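import json

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def make_openpose_json(triplets, extra_people=()):
    """Build one OpenPose-dialect frame document from 25 (x, y, c) triplets."""
    flat = [v for t in triplets for v in t]
    people = [{"pose_keypoints_2d": flat}]
    for person in extra_people:
        people.append({"pose_keypoints_2d": [v for t in person for v in t]})
    return json.dumps({"version": 1.4, "people": people})


@pytest.fixture
def rng():
    return np.random.default_rng(20240)


@pytest.fixture
def still_trial():
    """A quiet 10 s trial: mild sway and droop, no fall, no dropout."""
    from birddog import TrialParams, generate_trial

    params = TrialParams(
        sway_sigma=0.002, droop_deg=8.0, fall_time_s=None,
        dropout_rate=0.0, fps=30.0, duration_s=10.0, seed=7,
    )
    return generate_trial(params)


@pytest.fixture
def small_cohort():
    """An 8-participant (16-trial) cohort with short recordings."""
    from birddog import CohortConfig, generate_cohort

    cfg = CohortConfig(n_participants=8, duration_s=30.0, fps=15.0, master_seed=11)
    return generate_cohort(cfg)
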