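import pytest

from qlus.data import augment_with_unlisted_negatives, load_table1_fixture


@pytest.fixture(scope="session")
def fixture_table():
    """The embedded 49-row cohort."""
    return load_table1_fixture()


@pytest.fixture(scope="session")
def cohort64(fixture_table):
    """The full 64-hemithorax cohort: 49 printed rows + 15 reconstructed negatives."""
    return augment_with_unlisted_negatives(fixture_table, n=15, gu_fill=39.0)
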