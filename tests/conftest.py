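import numpy as np
import pytest

from diffhomeo.experiments import REDUCED, experiment_steady_and_linearity


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def steady_state_trio():
    """Steady-state networks for the three homeostatic conditions.

    One desk-scale run per condition (calibration, homeostasis to steady
    state, frozen probes); shared across the acceptance-level tests that
    compare rate distributions, response linearity, and decoding.
    """
    return experiment_steady_and_linearity(seed=7, scale=REDUCED)
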