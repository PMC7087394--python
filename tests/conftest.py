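import numpy as np
import pandas as pd
import pytest

import mrphewas as mp


@pytest.fixture(scope="session")
def panel60():
    return mp.simulate_panel(60, seed=11)


@pytest.fixture(scope="session")
def cohort60(panel60):
    cohort = mp.simulate_cohort(panel60, 8000, seed=11)
    return mp.attach_panel(cohort, panel60)


@pytest.fixture(scope="session")
def score60(panel60, cohort60):
    return mp.compute_grs(cohort60.dosages, panel60.set_index("rsid")["beta_exposure"])


def toy_mr_input():
    """Hand-sized harmonized summary table used across estimator tests."""
    return mp.mr_input_from_arrays(
        beta_exp=[0.10, 0.20, 0.30, 0.15, 0.25],
        se_exp=[0.01, 0.01, 0.01, 0.01, 0.01],
        beta_out=[0.05, 0.11, 0.14, 0.08, 0.12],
        se_out=[0.02, 0.03, 0.02, 0.025, 0.03],
    )


@pytest.fixture
def toy_input():
    return toy_mr_input()
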