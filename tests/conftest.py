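import pytest

from radsorb import reference_fixtures
from radsorb.models import KineticModel
from radsorb.synthetic import default_schedule


@pytest.fixture(scope="session")
def fixtures():
    return reference_fixtures()


@pytest.fixture(scope="session")
def nhap(fixtures):
    return fixtures["nHAp"]


@pytest.fixture(scope="session")
def ntio2(fixtures):
    return fixtures["nTiO2"]


@pytest.fixture(scope="session")
def schedule():
    return default_schedule()


@pytest.fixture(params=list(KineticModel), ids=lambda m: m.value)
def any_model(request):
    return request.param
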