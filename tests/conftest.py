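"""Shared fixtures: one synthetic run of the gradient experiment and one
test-mode fit of each model, reused across the suite (fits are the
expensive pieces; everything else is cheap)."""

from __future__ import annotations

import numpy as np
import pytest

import urchintherm as ut
from urchintherm.gonad_model import GonadModelSpec, fit_gonad_model
from urchintherm.stage_model import StageModelSpec, fit_stage_model

DATA_SEED = 0
FIT_SEED = 0

#: Generating stage-IV truth for the cells the analysis reports.
TRUTH_P4 = {
    ("F", "lanina"): 0.89,
    ("F", "elnino"): 0.15,
    ("M", "lanina"): 0.92,
    ("M", "elnino"): 0.44,
    ("M", "20C"): 0.812,
    ("F", "20C"): 0.25,
}


@pytest.fixture(scope="session")
def exp1_data():
    return ut.simulate_experiment1(seed=DATA_SEED)


@pytest.fixture(scope="session")
def stage_fits(exp1_data):
    """Test-mode stage-model fits of three replicate simulated runs.

    A single cell of ~30 animals carries binomial noise of ~0.05 on an
    extreme stage-IV share, so per-cell recovery is checked on the
    replicate-averaged posterior mean; contrasts use the first replicate.
    """
    fits = [fit_stage_model(exp1_data, StageModelSpec.exp1(mode="test"), seed=FIT_SEED)]
    for k in (1, 2):
        data = ut.simulate_experiment1(seed=DATA_SEED + k)
        fits.append(fit_stage_model(data, StageModelSpec.exp1(mode="test"), seed=FIT_SEED + k))
    return fits


@pytest.fixture(scope="session")
def stage_fit(stage_fits):
    """Test-mode stage-model fit of the default gradient-experiment run."""
    return stage_fits[0]


@pytest.fixture(scope="session")
def gonad_fit(exp1_data):
    """Test-mode gonad-model fit of the same run."""
    return fit_gonad_model(exp1_data, GonadModelSpec(mode="test"), seed=FIT_SEED)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
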