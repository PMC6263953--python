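import pytest

from fuzzyrehab.profiles import default_fis4d, default_fis4h, default_profile
from fuzzyrehab.session import make_demo_exercise


@pytest.fixture(scope="session")
def profile():
    return default_profile()


@pytest.fixture(scope="session")
def fis4h():
    return default_fis4h()


@pytest.fixture(scope="session")
def fis4d():
    return default_fis4d()


@pytest.fixture(scope="session")
def demo_exercise():
    return make_demo_exercise()
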