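import pytest

from cervicost import default_registry


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture(scope="session")
def means(registry):
    return registry.means()
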