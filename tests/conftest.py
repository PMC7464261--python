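import pytest
from hypothesis import settings

from afacs import default_coronary_table, default_graph, load_scenario

settings.register_profile("default", derandomize=True, max_examples=60)
settings.load_profile("default")
from afacs.risk_engine import StrokeRiskTable


@pytest.fixture(scope="session")
def scenario():
    return load_scenario()


@pytest.fixture(scope="session")
def graph():
    return default_graph()


@pytest.fixture(scope="session")
def coronary_table():
    return default_coronary_table()


@pytest.fixture(scope="session")
def stroke_table():
    return StrokeRiskTable()


@pytest.fixture(scope="session")
def stroke_table_full():
    return StrokeRiskTable.extended()
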