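import copy

import pytest

from hbocsim.parameters import default_parameters


@pytest.fixture(scope="session")
def params():
    return default_parameters()


@pytest.fixture()
def params_copy():
    return copy.deepcopy(default_parameters())
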