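import warnings

import pytest

from sotalolpbpk import distribution, physiology
from sotalolpbpk.absorption import AbsorptionSettings, calibrate_permeability


@pytest.fixture(scope="session")
def adult_male():
    return physiology.reference_adult_profile("male", 70.0)


@pytest.fixture(scope="session")
def sotalol_a():
    return distribution.sotalol_parameters("variant_a")


@pytest.fixture(scope="session")
def sotalol_b():
    return distribution.sotalol_parameters("variant_b")


@pytest.fixture(scope="session")
def kpset_a(sotalol_a, adult_male):
    return distribution.compute_kp_set(sotalol_a, adult_male)


@pytest.fixture(scope="session")
def calibration():
    """Permeability calibrated once (simulated AUC-ratio root find) for the session."""
    return calibrate_permeability(0.90)


@pytest.fixture(scope="session")
def calibrated_absorption(calibration):
    return AbsorptionSettings().with_permeability(calibration.effective_permeability)


@pytest.fixture(autouse=True)
def _silence_variant_b_warning():
    with warnings.catch_warnings():
        warnings.filterwarnings(
            "ignore", message=".*acidic-phospholipid affinity clamped.*")
        yield
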