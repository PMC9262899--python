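import numpy as np
import pytest
from hypothesis import settings

from coordsim.model import default_fixture
from coordsim.pipeline import run_emg_informed
from coordsim.solver import ObjectiveSpec, solve_trial
from coordsim.synth import generate_emg, generate_trial

settings.register_profile("suite", derandomize=True, max_examples=25)
settings.load_profile("suite")

SEED = 1


@pytest.fixture(scope="session")
def model():
    return default_fixture()


@pytest.fixture(scope="session")
def trial_truth(model):
    return generate_trial(model, seed=SEED)


@pytest.fixture(scope="session")
def natural_solution(model, trial_truth):
    trial, _ = trial_truth
    return solve_trial(model, trial, ObjectiveSpec("natural"))


@pytest.fixture(scope="session")
def avoidance_solution(model, trial_truth):
    trial, _ = trial_truth
    return solve_trial(model, trial, ObjectiveSpec("gastroc_avoidance"))


@pytest.fixture(scope="session")
def emg_bundle(trial_truth):
    """Raw and MVC EMG for the session trial."""
    _, truth = trial_truth
    raw, mvc = generate_emg(truth, fs=2000.0)
    return raw, mvc, 2000.0


@pytest.fixture(scope="session")
def emg_informed_report(model, trial_truth):
    trial, truth = trial_truth
    return run_emg_informed(model, trial, truth)
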