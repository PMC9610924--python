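import pytest

from banhatti import nbo2_partition, mof_partition, random_bounded_degree_graph


@pytest.fixture(scope="session")
def nbo2_22():
    return nbo2_partition(2, 2)


@pytest.fixture(scope="session")
def mof_22():
    return mof_partition(2, 2)


@pytest.fixture(scope="session")
def random_fixture():
    """The canonical bounded-degree oracle fixture (n=60, dmax=4, seed=7)."""
    return random_bounded_degree_graph(60, 4, 7)
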