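import pytest
from hypothesis import settings

from placentox import load_preset

settings.register_profile("default", derandomize=True, max_examples=100)
settings.load_profile("default")


@pytest.fixture(scope="session")
def human():
    return load_preset("human-T3")


@pytest.fixture(scope="session")
def mouse():
    return load_preset("mouse-E17.5")


@pytest.fixture(scope="session", params=["human-T3", "mouse-E17.5"])
def preset(request):
    return load_preset(request.param)
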