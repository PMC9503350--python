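import dataclasses

import numpy as np
import pytest

from adipoquant import CohortConfig, FrameSchedule, Tac, generate_cohort
from adipoquant.pipeline import quantify_bundle
from adipoquant.synthetic import _frame_average, blood_curve


@pytest.fixture(scope="session")
def default_config():
    return CohortConfig()


@pytest.fixture(scope="session")
def default_schedule(default_config):
    return FrameSchedule(
        np.asarray(default_config.frame_start, float),
        np.asarray(default_config.frame_duration, float),
    )


@pytest.fixture(scope="session")
def default_blood_tac(default_config, default_schedule):
    """Noise-free frame-averaged blood TAC of the default input function."""
    avg = _frame_average(lambda t: blood_curve(default_config.blood, t), default_schedule)
    return Tac(default_schedule, avg, "blood")


@pytest.fixture(scope="session")
def small_bundle():
    """A quick cohort (4 animals per cell) for smoke-level checks."""
    cfg = dataclasses.replace(CohortConfig(), n_per_cell=4, seed=7)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def cohort500():
    """Large cohort (500 per cell, seed 0): the association-recovery scale."""
    cfg = dataclasses.replace(CohortConfig(), n_per_cell=500, seed=0)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def cohort500_kinetics(cohort500):
    kin = quantify_bundle(cohort500).set_index("animal_id")
    return kin.rename(columns={"bat_sat_gu_ratio": "bat_sat_ratio"})
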