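import pytest

from coumascreen.fragments import default_class_rules, default_loss_catalog
from coumascreen.library import starter_library


@pytest.fixture(scope="session")
def catalog():
    return default_loss_catalog()


@pytest.fixture(scope="session")
def rules():
    return default_class_rules()


@pytest.fixture(scope="session")
def lib():
    return starter_library()


@pytest.fixture(scope="session")
def scopoletin(lib):
    return lib.get("scopoletin")


@pytest.fixture(scope="session")
def isofraxidin(lib):
    return lib.get("isofraxidin")
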