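import pytest
from hypothesis import settings

from pulmostage import Pipeline, load_decision_table, load_lexicon, load_modifiers
from pulmostage.preprocessing import load_section_policy

settings.register_profile("ci", derandomize=True, max_examples=60, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def lexicon():
    return load_lexicon()


@pytest.fixture(scope="session")
def modifiers():
    return load_modifiers()


@pytest.fixture(scope="session")
def table():
    return load_decision_table()


@pytest.fixture(scope="session")
def policy():
    return load_section_policy()


@pytest.fixture(scope="session")
def pipeline():
    return Pipeline()
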