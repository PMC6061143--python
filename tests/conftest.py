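import pytest
from hypothesis import settings

from aviprey import default_biome_table, read_summary_table

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def biome_table():
    """The canonical seven-biome parameter table."""
    return default_biome_table()


@pytest.fixture(scope="session")
def summaries():
    """Per-biome consumption summaries from the packaged printed table."""
    return read_summary_table()
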