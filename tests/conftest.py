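import pytest

from turnerscreen import (
    synthetic_birthweight_reference,
    synthetic_female_height_reference,
)


@pytest.fixture(scope="session")
def height_ref():
    return synthetic_female_height_reference()


@pytest.fixture(scope="session")
def bw_ref():
    return synthetic_birthweight_reference()
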