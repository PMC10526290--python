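import numpy as np
import pytest

from plantargait import build_graph, default_layout, normalize_adjacency


@pytest.fixture(scope="session")
def units():
    return default_layout()


@pytest.fixture(scope="session")
def graph(units):
    return build_graph(units)


@pytest.fixture(scope="session")
def norm(graph):
    return normalize_adjacency(graph)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
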