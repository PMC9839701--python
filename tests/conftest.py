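"""Shared fixtures: tiny hand-built networks and small synthetic cohorts."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from gutnet.io import SignedNetwork
from gutnet.simulate import BlockSpec, SyntheticConfig


def make_network(edges, nodes=None, name="toy"):
    """Build a SignedNetwork from (u, v, weight) triples."""
    g = nx.Graph()
    if nodes:
        g.add_nodes_from(nodes)
    for u, v, w in edges:
        g.add_edge(u, v, weight=float(w), q=0.01)
    for n in g.nodes:
        g.nodes[n].setdefault("mean_abundance", 1.0)
    return SignedNetwork(graph=g, name=name)


def clique_edges(nodes, weight=1.0):
    return [(a, b, weight) for i, a in enumerate(nodes)
            for b in nodes[i + 1:]]


@pytest.fixture
def two_cliques_net():
    """Two disjoint 5-cliques with unit positive weights."""
    a = [f"a{i}" for i in range(5)]
    b = [f"b{i}" for i in range(5)]
    return make_network(clique_edges(a) + clique_edges(b)), a, b


@pytest.fixture
def small_cohort():
    """A compact cohort with one strong planted block and fillers."""
    cfg = SyntheticConfig(
        n_subjects_per_group=4,
        n_species=20,
        blocks=(BlockSpec(0, 5, 0.8),),
        zero_inflation_prob=0.05,
        seed=42,
    )
    from gutnet.simulate import generate_cohort
    table, metadata, truth = generate_cohort(cfg)
    return table, metadata, truth


def random_signed_graph(rng, n_nodes, p_edge=0.4, neg_frac=0.3):
    """Random signed network for oracle-equivalence tests."""
    g = nx.Graph()
    names = [f"n{i}" for i in range(n_nodes)]
    g.add_nodes_from(names)
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            if rng.random() < p_edge:
                w = rng.uniform(0.3, 1.0)
                if rng.random() < neg_frac:
                    w = -w
                g.add_edge(names[i], names[j], weight=w, q=0.01)
    return SignedNetwork(graph=g, name="random")


def iter_set_partitions(n):
    """All set partitions of range(n) as label arrays (restricted growth)."""
    labels = np.zeros(n, dtype=int)
    maxes = np.zeros(n, dtype=int)
    while True:
        yield labels.copy()
        i = n - 1
        while i > 0 and labels[i] == maxes[i - 1] + 1:
            i -= 1
        if i == 0:
            return
        labels[i] += 1
        maxes[i] = max(maxes[i - 1], labels[i])
        for j in range(i + 1, n):
            labels[j] = 0
            maxes[j] = maxes[i]
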