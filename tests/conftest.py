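"""Shared fixtures: small hand-built networks and random network factories."""

from __future__ import annotations

import numpy as np
import pytest

from hetlink.hetnet import AttributeSpec, HeterogeneousNetwork, NetworkSchema


def small_schema(with_direct: bool = True) -> NetworkSchema:
    edge_types = {
        "ncRNA-gene": ("ncRNA", "gene"),
        "gene-disease": ("gene", "disease"),
    }
    if with_direct:
        edge_types["ncRNA-disease"] = ("ncRNA", "disease")
    return NetworkSchema(
        node_types={
            "ncRNA": [
                AttributeSpec("expression", "numeric"),
                AttributeSpec("biotype", "categorical"),
            ],
            "disease": [AttributeSpec("prevalence", "numeric")],
            "gene": [AttributeSpec("conservation", "numeric")],
        },
        target_types=("ncRNA", "disease"),
        edge_types=edge_types,
    )


def random_network(seed: int, with_direct: bool = True) -> HeterogeneousNetwork:
    """A small random attributed network (<= 30 nodes) over the 3-type
    schema, with ~10% missing attribute cells.  No off-path node types, so
    attribute propagation is a no-op and the brute-force oracle applies."""
    rng = np.random.default_rng(seed)
    n_n = int(rng.integers(3, 8))
    n_d = int(rng.integers(3, 8))
    n_g = int(rng.integers(2, 6))

    def maybe(v):
        return None if rng.random() < 0.1 else v

    nodes = {
        "ncRNA": {
            f"n{i}": {
                "expression": maybe(float(np.round(rng.uniform(0, 10), 3))),
                "biotype": maybe(str(rng.choice(["mirna", "lncrna"]))),
            }
            for i in range(n_n)
        },
        "disease": {
            f"d{i}": {"prevalence": maybe(float(np.round(rng.uniform(0, 5), 3)))}
            for i in range(n_d)
        },
        "gene": {
            f"g{i}": {"conservation": maybe(float(np.round(rng.uniform(0, 1), 3)))}
            for i in range(n_g)
        },
    }

    def bernoulli_edges(left, right, p):
        return {
            (a, b)
            for a in left
            for b in right
            if rng.random() < p
        }

    edges = {
        "ncRNA-gene": bernoulli_edges(nodes["ncRNA"], nodes["gene"], 0.3),
        "gene-disease": bernoulli_edges(nodes["gene"], nodes["disease"], 0.3),
    }
    if with_direct:
        edges["ncRNA-disease"] = bernoulli_edges(nodes["ncRNA"], nodes["disease"], 0.15)
    return HeterogeneousNetwork(
        schema=small_schema(with_direct), nodes=nodes, edges=edges
    )


@pytest.fixture
def toy_net() -> HeterogeneousNetwork:
    """2 ncRNAs, 2 diseases, 1 gene, 3 edges — the minimal loading example."""
    return HeterogeneousNetwork(
        schema=small_schema(),
        nodes={
            "ncRNA": {
                "n1": {"expression": 2.0, "biotype": "mirna"},
                "n2": {"expression": 4.0, "biotype": "lncrna"},
            },
            "disease": {
                "d1": {"prevalence": 1.0},
                "d2": {"prevalence": 3.0},
            },
            "gene": {"g1": {"conservation": 0.5}},
        },
        edges={
            "ncRNA-gene": {("n1", "g1")},
            "gene-disease": {("g1", "d1")},
            "ncRNA-disease": {("n1", "d2")},
        },
    )
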