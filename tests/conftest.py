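import numpy as np
import pytest

from gfalayout import Edge, Handle, Node, Path, VariationGraph, build_path_index

_SEQ = "ACGTACGTACGTACGTACGTACGTACGTACGT"


def linear_graph(lengths, path_name="p"):
    """Deterministic linear chain with the given node lengths, one path."""
    nodes = [
        Node(i + 1, (_SEQ * (ln // len(_SEQ) + 1))[:ln]) for i, ln in enumerate(lengths)
    ]
    edges = [Edge(Handle(i), Handle(i + 1)) for i in range(1, len(lengths))]
    path = Path(path_name, [Handle(i) for i in range(1, len(lengths) + 1)])
    return VariationGraph(nodes, edges, [path])


@pytest.fixture
def tiny_graph():
    """The (3,5,2) linear fixture used across modules."""
    return linear_graph([3, 5, 2])


@pytest.fixture
def tiny_index(tiny_graph):
    return build_path_index(tiny_graph)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
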