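import pytest

from mfpbpk.drug import BUPRENORPHINE, DEFAULT_SALIVARY_MODEL, SOLUTION, TABLET
from mfpbpk.simulator import Physiology, Regimen


@pytest.fixture(scope="session")
def drug():
    return BUPRENORPHINE


@pytest.fixture(scope="session")
def tablet():
    return TABLET


@pytest.fixture(scope="session")
def solution():
    return SOLUTION


@pytest.fixture(scope="session")
def salivary_model():
    return DEFAULT_SALIVARY_MODEL


@pytest.fixture(scope="session")
def physiology():
    return Physiology()


@pytest.fixture(scope="session")
def bid_regimen_14d():
    """Twice-daily 8 mg for 14 days (pseudo-steady-state regimen)."""
    return Regimen(dose_mg=8.0, interval_h=12.0, n_doses=28)
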