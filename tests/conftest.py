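"""Shared fixtures: small canonical graphs and random-graph generators."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from pagdiscover.graph import Mark, MixedGraph


def make_dag(nodes, edges, latent=()):
    """DAG from an edge list of (parent, child) pairs."""
    g = MixedGraph(kind="DAG")
    for n in nodes:
        g.add_node(n, latent=n in latent)
    for p, c in edges:
        g.add_edge(p, c, Mark.TAIL, Mark.ARROW)
    return g


def random_dag(rng, n_observed, n_latent=0, p_edge=0.4):
    """Random DAG; latents are roots with exactly two observed children."""
    obs = [f"V{i}" for i in range(n_observed)]
    order = [obs[i] for i in rng.permutation(n_observed)]
    edges = [(order[i], order[j])
             for i, j in itertools.combinations(range(n_observed), 2)
             if rng.random() < p_edge]
    lat = [f"L{i}" for i in range(n_latent)]
    g = make_dag(obs, edges)
    for name in lat:
        g.add_node(name, latent=True)
        ch = rng.choice(n_observed, size=2, replace=False)
        for c in ch:
            g.add_edge(name, obs[c], Mark.TAIL, Mark.ARROW)
    return g


@pytest.fixture
def y_structure():
    """X1→Z←X2, Z→W: the classic visible-edge fixture."""
    return make_dag(["X1", "X2", "Z", "W"],
                    [("X1", "Z"), ("X2", "Z"), ("Z", "W")])


@pytest.fixture
def two_collider_latent():
    """A→B←L→C←D with L latent: forces B↔C in the PAG."""
    return make_dag(["A", "B", "C", "D", "L"],
                    [("A", "B"), ("L", "B"), ("L", "C"), ("D", "C")],
                    latent={"L"})


@pytest.fixture
def chain4():
    return make_dag(list("ABCD"), [("A", "B"), ("B", "C"), ("C", "D")])
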