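import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # makes `oracle` importable

from pathpersist import FilteredDigraph, PathwayNetwork, toy_filtered_digraph, toy_network


@pytest.fixture
def toy():
    return toy_network()


@pytest.fixture
def toy_fg():
    return toy_filtered_digraph()


def make_network(edges, extra_nodes=(), pathway_id="net"):
    """PathwayNetwork from bare (source, target) pairs."""
    nodes = list(dict.fromkeys([v for e in edges for v in e] + list(extra_nodes)))
    return PathwayNetwork(
        pathway_id=pathway_id,
        nodes=nodes,
        edges=[(s, t, "other") for s, t in edges],
    )


def make_filtered(edges_with_weights, extra_nodes=(), condition="C"):
    """FilteredDigraph from {(source, target): weight}."""
    net = make_network(list(edges_with_weights), extra_nodes)
    return FilteredDigraph(
        network=net, edge_weights=dict(edges_with_weights), condition=condition
    )


def random_filtered(rng, n_nodes=5, p_edge=0.35, condition="C"):
    """Random weighted digraph with grid-snapped weights."""
    nodes = [f"v{i}" for i in range(n_nodes)]
    weights = {}
    for a in nodes:
        for b in nodes:
            if a != b and rng.random() < p_edge:
                weights[(a, b)] = round(float(rng.integers(0, 101)) / 100, 2)
    return make_filtered(weights, extra_nodes=nodes, condition=condition)
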