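import pytest

from activeq.activity_catalog import default_catalog
from activeq.config import default_config
from activeq.questionnaire import ParticipantProfile


@pytest.fixture(scope="session")
def catalog():
    return default_catalog()


@pytest.fixture(scope="session")
def config():
    return default_config()


@pytest.fixture(scope="session")
def category_map(config):
    return config.categories


@pytest.fixture(scope="session")  # frozen dataclass: safe to share across examples
def profile():
    return ParticipantProfile(
        participant_id="P0001", sex="female", age_years=28, weight_kg=60.0,
        height_cm=166.0,
    )
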