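import numpy as np
import pytest

from spiroprm import simulate, spirometry


@pytest.fixture(scope="session")
def small_cohort():
    """Quarter-scale synthetic cohort shared across tests (fixed seed)."""
    calib = simulate.scaled_calibration(simulate.DEFAULT_CALIBRATION, 0.25)
    return simulate.generate_cohort(calib, seed=12345)


@pytest.fixture(scope="session")
def derived_cohort(small_cohort):
    subjects, _, _ = small_cohort
    derived = spirometry.derive_spirometry(subjects)
    derived["group"] = spirometry.assign_groups(derived, group4_mode=None)
    return derived


@pytest.fixture(scope="session")
def normative_bed():
    return simulate.generate_normative_truth(1500, seed=777)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
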