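import pytest
from hypothesis import settings

from mucoperm import get_preset

settings.register_profile("mucoperm", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("mucoperm")


@pytest.fixture(scope="session")
def moxi():
    return get_preset("moxifloxacin_table1")


@pytest.fixture(scope="session")
def ethio():
    return get_preset("ethionamide_table1")
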