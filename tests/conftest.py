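import numpy as np
import pandas as pd
import pytest

from solmark.simulate import CohortConfig, simulate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """One default-calibration synthetic cohort shared across tests."""
    return simulate_cohort(CohortConfig(), seed=20240201)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def small_panel():
    """Tiny biomarker panel with one excluded subject and one censorable ion."""
    return pd.DataFrame(
        {
            "subject_id": ["a", "b", "c", "d"],
            "solanidine": [0.5, 0.005, 1.0, 0.02],
            "mz414": [2.0, 1.0, 0.0005, 3.0],
            "mz412": [0.5, 0.5, 0.5, -1.0],
        }
    )
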