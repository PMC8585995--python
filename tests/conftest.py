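import pytest

from ddscreen import (
    CohortSpec,
    generate_cohort,
    load_default_instrument,
)


@pytest.fixture(scope="session")
def sadd():
    return load_default_instrument("sadd")


@pytest.fixture(scope="session")
def dast10():
    return load_default_instrument("dast10")


@pytest.fixture(scope="session")
def ddsi():
    return load_default_instrument("ddsi")


@pytest.fixture(scope="session")
def small_cohort():
    """A 250-patient synthetic cohort at the default (published) margins."""
    return generate_cohort(CohortSpec(n=250, seed=20170201))


@pytest.fixture()
def valid_record_doc():
    return {
        "record_id": "P-001",
        "age": 31,
        "sex": "male",
        "education": "high_school",
        "marital_status": "single",
        "income_source": "employment",
        "days_in_residence": 10,
        "substance_use": [],
    }
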