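import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from phylodiscord import parse_newick, potentilla_fixture


@pytest.fixture(scope="session")
def fixture():
    return potentilla_fixture()


@pytest.fixture
def four_leaf_tree():
    return parse_newick("((A:0.1,B:0.2)1.0:0.05,(C:0.3,D:0.15)1.0:0.07);")


@pytest.fixture
def caterpillar6():
    return parse_newick(
        "(((((A:1,B:1)1.0:1,C:1)1.0:1,D:1)1.0:1,E:1)1.0:1,F:1);"
    )
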