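import pytest

from synlib.design import uniform_library_design
from synlib.scaffold import default_scaffold


@pytest.fixture(scope="session")
def template():
    return default_scaffold()


@pytest.fixture(scope="session")
def library(template):
    return uniform_library_design(template)
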