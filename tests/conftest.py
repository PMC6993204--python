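import numpy as np
import pytest

from needledrive.synthetic import (
    NoiseParams,
    SyntheticTrialConfig,
    default_geometry,
    generate_trial,
)
from needledrive.trial import SegmentedTrial, SubtaskLabel, UniformTrial


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def geometry():
    return default_geometry()


@pytest.fixture(scope="session")
def noiseless_config():
    return SyntheticTrialConfig(noise=NoiseParams(0, 0, 0, 0), seed=0)


@pytest.fixture(scope="session")
def canonical_trial(geometry):
    """insert -> reposition -> extract trial with default (small) noise."""
    cfg = SyntheticTrialConfig(seed=3)
    return generate_trial(cfg, geometry)


def make_uniform_trial(t, position, orientation=None, velocity=None,
                       acceleration=None, jerk=None, force=None, torque=None,
                       gripper=None, rate=None):
    """Hand-assembled UniformTrial for metric unit tests."""
    t = np.asarray(t, dtype=float)
    n = len(t)
    if orientation is None:
        orientation = np.tile([1.0, 0, 0, 0], (n, 1))
    if rate is None:
        rate = 1.0 / (t[1] - t[0])
    return UniformTrial(
        t=t,
        position=np.asarray(position, dtype=float),
        orientation=orientation,
        gripper=np.zeros(n) if gripper is None else gripper,
        force=np.zeros((n, 3)) if force is None else force,
        torque=np.zeros((n, 3)) if torque is None else torque,
        meta={"rate": rate},
        rate=rate,
        velocity=velocity,
        acceleration=acceleration,
        jerk=jerk,
    )


def whole_trial_segment(trial):
    """SegmentedTrial covering the entire trial as one insertion run."""
    labels = np.full(len(trial), int(SubtaskLabel.INSERTION))
    return SegmentedTrial(trial=trial, bounds=(0, len(trial) - 1), labels=labels)
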