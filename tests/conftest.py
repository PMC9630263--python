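import numpy as np
import pytest

from divekin import default_params, simulate_dive
from divekin.pipeline import ProcessConfig, process_trial


@pytest.fixture(scope="session")
def clean_new_rule():
    """Noise-free new-rule trial with its ground truth."""
    params = default_params("new", "right")
    rec, truth = simulate_dive(params)
    return params, rec, truth


@pytest.fixture(scope="session")
def clean_old_rule():
    params = default_params("old", "right")
    rec, truth = simulate_dive(params)
    return params, rec, truth


@pytest.fixture(scope="session")
def clean_outcomes(clean_new_rule):
    """Pipeline outcomes of the clean trial, no filtering."""
    _, rec, _ = clean_new_rule
    cfg = ProcessConfig(cm_cutoff_hz=None, force_cutoff_hz=None)
    return process_trial(rec, cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
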