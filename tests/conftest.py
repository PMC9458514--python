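import dataclasses

import numpy as np
import pytest

from pdac_cea import ARM_FOLFIRINOX, ARM_GNP, ARM_NATURAL_HISTORY
from pdac_cea.pipeline import calibrate_all, load_inputs, run_base_case


@pytest.fixture(scope="session")
def inputs():
    return load_inputs()


@pytest.fixture(scope="session")
def calibrations(inputs):
    return calibrate_all(inputs, seed=1)


@pytest.fixture(scope="session")
def base_run(inputs, calibrations):
    return run_base_case(inputs, seed=1, calibrations=calibrations)


@pytest.fixture(scope="session")
def folfirinox(inputs):
    return inputs.strategy(ARM_FOLFIRINOX)


@pytest.fixture(scope="session")
def gnp(inputs):
    return inputs.strategy(ARM_GNP)


@pytest.fixture(scope="session")
def natural_history(inputs):
    return inputs.strategy(ARM_NATURAL_HISTORY)


@pytest.fixture
def zero_background(inputs):
    """No all-cause mortality: isolates disease hazards in toy models."""
    return np.zeros(inputs.settings.horizon_cycles)


@pytest.fixture
def short_settings(inputs):
    """Small-horizon settings for closed-form toy checks."""
    return dataclasses.replace(inputs.settings, horizon_cycles=24)
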