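import pytest

import crccea


@pytest.fixture(scope="session")
def fixture():
    """Packaged study tables, checksum-verified once per session."""
    return crccea.load_paper_fixture()


@pytest.fixture(scope="session")
def pipeline_results():
    """Full pipeline run on the packaged tables."""
    return crccea.run_pipeline(crccea.RunConfig(gdp_per_capita=11414.0))


@pytest.fixture(scope="session")
def toy_value_set():
    return crccea.linear_toy_value_set()
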