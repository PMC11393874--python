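import pytest

from repairvar import (FilterConfig, load_default_panel, load_table1_fixture,
                       load_table2_fixture)
from repairvar.gene_panel import PanelIndex


@pytest.fixture(scope="session")
def table1():
    return load_table1_fixture()


@pytest.fixture(scope="session")
def table2():
    return load_table2_fixture()


@pytest.fixture(scope="session")
def panel():
    return load_default_panel()


@pytest.fixture(scope="session")
def panel_index(panel):
    return PanelIndex(panel)


@pytest.fixture(scope="session")
def published():
    return FilterConfig.published()
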