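import pytest

from skelage import table1_fixture


@pytest.fixture(scope="session")
def fixture_dataset():
    """The reconstructed published-study dataset (31 records)."""
    return table1_fixture()
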