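import numpy as np
import pytest

from gseachain import (RankedList, build_graph, generate_transactions,
                       worked_example)


@pytest.fixture(scope="session")
def we():
    return worked_example()


@pytest.fixture(scope="session")
def we_graph(we):
    return build_graph(we.records)


@pytest.fixture(scope="session")
def we_transactions(we, we_graph):
    return generate_transactions(we.genes, we_graph, max_len=we.max_len)


def make_ranked(genes, delta) -> RankedList:
    return RankedList(genes=np.asarray(list(genes), dtype=object),
                      delta=np.asarray(delta, dtype=float))


@pytest.fixture
def small_ranked():
    return make_ranked("WXYZ", [4.0, 3.0, 2.0, 1.0])
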