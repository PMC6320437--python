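import pytest

from monokb.fixtures import make_mini_ontokbcf


@pytest.fixture(scope="session")
def mini():
    """Compiled mini cystic-fibrosis fixture (KB + EHR config + pipeline steps)."""
    return make_mini_ontokbcf()


@pytest.fixture(scope="session")
def mini_kb(mini):
    return mini.kb
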