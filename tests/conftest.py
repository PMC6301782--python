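import numpy as np
import pytest

import pedzscore as pz


@pytest.fixture(scope="session")
def hfa_table():
    """Synthetic height-for-age LMS table, 1-month ages (L = 1 default trend)."""
    return pz.synth_lms_table(pz.MeasurementKind.HFA, np.arange(0.0, 240.5, 1.0), seed=7)


@pytest.fixture(scope="session")
def wfa_table():
    """Synthetic weight-for-age LMS table (skewed, L < 0)."""
    return pz.synth_lms_table(pz.MeasurementKind.WFA, np.arange(0.0, 240.5, 1.0), seed=7)


@pytest.fixture(scope="session")
def hfa_grid_coarse():
    """Coarse HFA grid (2 sexes x 11 ages x 9 z-levels = 198 points)."""
    table = pz.synth_lms_table(pz.MeasurementKind.HFA, np.arange(0.0, 241.0, 24.0), seed=7)
    return pz.grid_from_lms(table)


@pytest.fixture(scope="session")
def gp_hfa_coarse(hfa_grid_coarse):
    """Squared-exponential GP fitted once per session on the coarse HFA grid."""
    res, _ = pz.gp_fit(hfa_grid_coarse, seed=0, n_restarts=2, maxiter=120)
    return res


class StubGP:
    """Test double standing in for a fitted GP: returns preset z-scores."""

    def __init__(self, fn):
        self.fn = fn

    def predict(self, sex, age_months, value):
        z = np.asarray(self.fn(np.asarray(sex), np.asarray(age_months, dtype=float),
                                np.asarray(value, dtype=float)), dtype=float)
        return z, np.zeros_like(z)


@pytest.fixture
def stub_gp_factory():
    return StubGP
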