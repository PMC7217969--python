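import pytest

from slnet.network import GeneSetCollection, InteractionNetwork


@pytest.fixture
def path_net():
    """A-B, B-C, C-D path network."""
    net = InteractionNetwork()
    net.add_edge("A", "B")
    net.add_edge("B", "C")
    net.add_edge("C", "D")
    return net


@pytest.fixture
def clique5():
    net = InteractionNetwork()
    genes = ["A", "B", "C", "D", "E"]
    for i, a in enumerate(genes):
        for b in genes[i + 1 :]:
            net.add_edge(a, b)
    return net


def make_collection(mapping):
    coll = GeneSetCollection()
    for name, genes in mapping.items():
        coll.add(name, genes)
    return coll
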