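import numpy as np
import pytest

from phostf.networks import NodeSets, RegulatoryNetwork


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_nodes(n_pk=2, n_pp=1, n_tf=2, n_o=3) -> NodeSets:
    classes = {}
    for i in range(n_pk):
        classes[f"K{i}"] = "PK"
    for i in range(n_pp):
        classes[f"F{i}"] = "PP"
    for i in range(n_tf):
        classes[f"T{i}"] = "TF"
    for i in range(n_o):
        classes[f"O{i}"] = "O"
    return NodeSets.from_classes(classes)


def random_network(rng, n_pk=2, n_pp=1, n_tf=2, n_o=3, scale=0.2,
                   density=1.0) -> RegulatoryNetwork:
    """Random weights on the full class-consistent masks, stable P block."""
    nodes = make_nodes(n_pk, n_pp, n_tf, n_o)
    shell = RegulatoryNetwork(nodes, np.zeros((nodes.n, nodes.n)))
    allowed = shell.M_T | shell.M_P
    W = np.zeros((nodes.n, nodes.n))
    vals = rng.normal(0, scale, size=int(allowed.sum()))
    if density < 1.0:
        vals *= rng.random(vals.size) < density
    W[allowed] = vals
    return shell.copy_with(W)


@pytest.fixture
def small_net(rng):
    return random_network(rng)
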