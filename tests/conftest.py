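import numpy as np
import pandas as pd
import pytest

from hbloss import CohortSimParams, CohortTable, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """Default-parameter synthetic cohort at the headline size (n=401)."""
    table, report = generate_cohort(CohortSimParams(n=401, seed=11))
    return table, report


@pytest.fixture(scope="session")
def big_cohort():
    """Calibration-scale cohort (n=5000) with no missingness."""
    table, report = generate_cohort(
        CohortSimParams(n=5000, seed=202, missing_post_cbc_rate=0.0)
    )
    return table, report


@pytest.fixture(scope="session")
def noisefree_cohort():
    """Noise-free cohort: the formula reproduces every observed loss exactly."""
    table, _ = generate_cohort(
        CohortSimParams(n=800, seed=33, loss_noise_sd=0.0, missing_post_cbc_rate=0.0)
    )
    return table


@pytest.fixture
def tiny_frame():
    """Hand-written three-donor frame covering both sexes and a missing hb_post."""
    return pd.DataFrame(
        {
            "donor_id": ["a", "b", "c"],
            "sex": ["female", "male", "male"],
            "height_cm": [170.0, 180.0, 176.0],
            "weight_kg": [65.0, 80.0, 75.0],
            "age": [30.0, 40.0, np.nan],
            "hb_pre": [140.0, 150.0, 148.0],
            "hb_post": [120.0, 125.0, np.nan],
            "hct_pre": [0.42, 0.45, 0.44],
            "hct_post": [0.36, 0.40, np.nan],
            "plt_pre": [250e3, 230e3, 240e3],
            "leuco_pre": [6000.0, 7000.0, 6500.0],
            "hb_loss_g": [80.0, 120.0, 100.0],
        }
    )


@pytest.fixture
def tiny_table(tiny_frame):
    return CohortTable(tiny_frame, provenance="fixture")
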