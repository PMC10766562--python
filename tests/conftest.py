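import numpy as np
import pytest
from hypothesis import settings

from trajgp.data import ALSFRSR, PatientTrajectory, add_onset_anchor
from trajgp.model import MixtureOfGPs, MoGPConfig
from trajgp.simulate import generate_cohort, two_group_linear_spec

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=40)
settings.load_profile("ci")


def make_traj(subject_id, t, y, scale=ALSFRSR, anchored=False, **meta):
    return PatientTrajectory.from_arrays(subject_id, t, y, scale, anchored=anchored,
                                         metadata=meta)


@pytest.fixture(scope="session")
def two_group_cohort():
    """Well-separated two-slope linear cohort with truth labels."""
    trajs, truth = generate_cohort(two_group_linear_spec(seed=11, size=12))
    return [add_onset_anchor(tr) for tr in trajs], truth


@pytest.fixture(scope="session")
def two_group_fit(two_group_cohort):
    trajs, _ = two_group_cohort
    return MixtureOfGPs(trajs, config=MoGPConfig(n_sweeps=20)).fit(seed=5)
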