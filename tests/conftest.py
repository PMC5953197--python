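import pytest

from mbrplan import Lesion, Patient, RadiobioParams


@pytest.fixture(scope="session")
def params() -> RadiobioParams:
    """Prostate-cancer default parameter set."""
    return RadiobioParams()


@pytest.fixture
def toy_patient() -> Patient:
    """Two-lesion toy patient: 10 ml at 1 Gy, 30 ml at 2 Gy (PMAD 1.5 Gy)."""
    return Patient("toy", (Lesion("a", 10.0, 1.0), Lesion("b", 30.0, 2.0)))


@pytest.fixture
def single_lesion_patient() -> Patient:
    """One 227 ml lesion (the median-burden patient) at 19 Gy."""
    return Patient("single", (Lesion("a", 227.0, 19.0),))
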