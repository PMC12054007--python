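import pytest

from hdrakit.classify import load_catalog
from hdrakit.synth import synthetic_molybdop_anchor, synthetic_reference_anchor


@pytest.fixture(scope="session")
def catalog():
    return load_catalog()


@pytest.fixture(scope="session")
def hdra_anchor():
    return synthetic_reference_anchor()


@pytest.fixture(scope="session")
def molybdop_anchor():
    return synthetic_molybdop_anchor()
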