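import pytest
from hypothesis import settings

from dmdframe import fixture_cohort, fixture_manifest, load_exon_table

settings.register_profile("suite", derandomize=True, max_examples=100)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def exon_table():
    return load_exon_table()


@pytest.fixture(scope="session")
def cohort():
    return fixture_cohort()


@pytest.fixture(scope="session")
def manifest():
    return fixture_manifest()
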