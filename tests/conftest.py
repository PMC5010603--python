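import datetime

import pytest

from hepatosafe.emr_model import default_study_config
from hepatosafe.lc_outcomes import default_catalog
from hepatosafe.synthetic_emr import generate_worked_fixture

D = datetime.date


@pytest.fixture(scope="session")
def study_config():
    return default_study_config()

@pytest.fixture(scope="session")
def catalog():
    return default_catalog()


@pytest.fixture(scope="session")
def fixture_dataset():
    return generate_worked_fixture()


def day(n: int) -> datetime.date:
    """Map an integer day offset onto a calendar date (day 0 = 2010-01-01)."""
    return D(2010, 1, 1) + datetime.timedelta(days=n)
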