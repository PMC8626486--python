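import warnings

import numpy as np
import pytest

from dattraj.synthetic_cohort import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A small but fully structured cohort shared by read-only tests."""
    cfg = SimulationConfig(n_controls=40, n_pd=60, seed=42)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cohort, truth, extras = simulate_cohort(cfg)
    return cfg, cohort, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)
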