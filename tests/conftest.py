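from datetime import date

import pytest
from hypothesis import settings

from ipflink import ValidationStudy, build_fixture

settings.register_profile("deterministic", derandomize=True, max_examples=50)
settings.load_profile("deterministic")
from ipflink.core import (
    ClinicalEvent,
    CodeList,
    CodeSystem,
    PatientRegistryRow,
    Rating,
    Sex,
)


@pytest.fixture(scope="session")
def fixture_cohort():
    """The deterministic marginal-matched dataset, linked once per session."""
    return build_fixture().link()


@pytest.fixture(scope="session")
def fixture_results(fixture_cohort):
    return ValidationStudy(fixture_cohort).fit()


@pytest.fixture
def rated_codelist():
    return CodeList(
        name="toy",
        system=CodeSystem.SNOMED_LIKE,
        entries=(
            ("N1", "highly specific", Rating.YES),
            ("B1", "generic one", Rating.MAYBE),
            ("B2", "generic two", Rating.MAYBE),
            ("X1", "rejected", Rating.NO),
        ),
    )


def make_registry_row(pid="P1", birth=date(1950, 1, 1), reg=date(2005, 1, 1),
                      death=None, transfer=None, last_collection=None,
                      sex=Sex.MALE):
    return PatientRegistryRow(
        patient_id=pid, birth_date=birth, sex=sex, registration_start=reg,
        last_collection_date=last_collection, transfer_out_date=transfer,
        death_date=death)


def make_event(pid="P1", day=date(2012, 5, 10), code="B1", term=""):
    return ClinicalEvent(pid, day, code, term)
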