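import pytest

from gumid import load_cases, load_replicas
from gumid.sugars import MarkerThresholds


@pytest.fixture(scope="session")
def replicas():
    return load_replicas()


@pytest.fixture(scope="session")
def cases():
    return load_cases()


@pytest.fixture(scope="session")
def thresholds():
    return MarkerThresholds()
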