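import pytest

from lvikit.aggregate import HouseholdRecord, SurveyDataset, build_indicator_table
from lvikit.datasets import default_precomputed
from lvikit.framework import default_framework
from lvikit.synthetic import default_choke_spec, generate_survey


@pytest.fixture(scope="session")
def fw():
    return default_framework()


@pytest.fixture(scope="session")
def spec():
    return default_choke_spec()


@pytest.fixture(scope="session")
def survey(spec):
    return generate_survey(spec, seed=7)


@pytest.fixture(scope="session")
def indicator_table(survey, fw):
    return build_indicator_table(survey, fw, precomputed=default_precomputed())


@pytest.fixture
def tiny_survey():
    """Two units, hand-countable responses."""
    records = [
        HouseholdRecord("h1", "U1", {"color": "red", "size": 1.0}),
        HouseholdRecord("h2", "U1", {"color": "red", "size": 1.2}),
        HouseholdRecord("h3", "U1", {"color": "blue", "size": 1.4}),
        HouseholdRecord("h4", "U2", {"color": "red", "size": 2.0}),
        HouseholdRecord("h5", "U2", {"size": 3.0}),  # missing color
    ]
    return SurveyDataset(records)
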