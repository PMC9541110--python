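import numpy as np
import pytest

from camforce.model_registry import load_default_model
from camforce.preprocess import default_regression
from camforce.synthetic_data import ExerciseProfile, NoiseModel, generate_ground_truth


@pytest.fixture(scope="session")
def model():
    return load_default_model()


@pytest.fixture(scope="session")
def regression():
    return default_regression()


@pytest.fixture()
def zero_noise():
    return NoiseModel.zero(seed=11)


@pytest.fixture(scope="session")
def curl_profile():
    return ExerciseProfile.biceps_curl(n_reps=2, rep_duration=2.0)


@pytest.fixture(scope="session")
def fly_profile():
    return ExerciseProfile.lateral_fly(n_reps=2, rep_duration=2.0)


@pytest.fixture(scope="session")
def curl_truth_100hz(model, curl_profile):
    return generate_ground_truth(curl_profile, model, seed=21, rate=100.0)


@pytest.fixture(scope="session")
def fly_truth_100hz(model, fly_profile):
    return generate_ground_truth(fly_profile, model, seed=22, rate=100.0)


def neutral_pose(model):
    return {c: 0.0 for c in model.chain.coordinate_names}


@pytest.fixture()
def neutral(model):
    return neutral_pose(model)


def random_pose(model, rng, scale=0.5):
    """A random pose comfortably inside all coordinate ranges."""
    pose = {}
    for c in model.chain.coordinates:
        lo, hi = c.range_deg
        mid = 0.5 * (lo + hi)
        half = 0.5 * (hi - lo) * scale
        pose[c.name] = float(mid + rng.uniform(-half, half))
    return pose
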