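import pytest

from derivid import default_rule_set, load_fixture


@pytest.fixture(scope="session")
def rules():
    return default_rule_set()


@pytest.fixture(scope="session")
def isomers():
    return load_fixture("c12h10o2_isomers")


@pytest.fixture(scope="session")
def validation_mix():
    return load_fixture("validation_mix")


@pytest.fixture(scope="session")
def all_records(isomers, validation_mix):
    return isomers.records + validation_mix.records
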