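import pytest

from apcscreen import run_screen
from apcscreen.simulate import make_fixture


@pytest.fixture(scope="session")
def tiny_fixture():
    return make_fixture(7, preset="tiny")


@pytest.fixture(scope="session")
def default_fixture():
    return make_fixture(11, preset="default")


@pytest.fixture(scope="session")
def default_report(default_fixture):
    return run_screen(default_fixture.screen_inputs(), default_fixture.config)
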