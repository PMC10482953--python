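import numpy as np
import pytest

from priorconf.evaluate import make_cohort_params, simulate_and_normalize
from priorconf.synthetic import ExperimentDesign


@pytest.fixture(scope="session")
def small_cohort():
    """Three simulated observers, one session (360 trials) each, with
    normalized strengths attached; true parameters returned alongside."""
    params = make_cohort_params(3, {"w_choice": 2.17, "w_conf": 1.27, "b": 2.18},
                                between_sd_log=0.2, seed=101)
    design = ExperimentDesign(n_participants=3, sessions=1, blocks_per_session=10)
    trials = simulate_and_normalize(params, design, seed=101)
    return params, trials


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
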