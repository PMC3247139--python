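import pytest

from plateletsig import (
    BasalConstants,
    DrugParameters,
    PlateletState,
    StimulusProtocol,
)
from plateletsig.synth import StudyDesign, true_drug_parameters


@pytest.fixture(scope="session")
def constants():
    return BasalConstants()


@pytest.fixture(scope="session")
def basal():
    return PlateletState()


@pytest.fixture(scope="session")
def truth_drugs():
    return true_drug_parameters()


@pytest.fixture()
def iloprost_protocol():
    return StimulusProtocol.single("Iloprost", 10.0)


@pytest.fixture()
def milrinone_protocol():
    return StimulusProtocol.single("Milrinone", 100.0)


@pytest.fixture(scope="session")
def small_design():
    """Two-drug, four-series design for fast fitting tests."""
    return StudyDesign(
        seed=17,
        doses={"Milrinone": (10.0, 100.0), "Iloprost": (10.0, 100.0)},
    )


@pytest.fixture(scope="session")
def default_drugs():
    return DrugParameters()
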