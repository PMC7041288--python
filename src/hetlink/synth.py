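"""Synthetic attributed heterogeneous networks with planted cluster structure.

The generator emulates the shape of ncRNA-disease evidence networks: an
ncRNA type and a disease type (the targets) joined directly and through a
gene layer, plus an optional protein layer hanging off the genes that no
meta-path reaches (so it only enters scoring through attribute
propagation).  Ground truth is planted as blocks: each cluster owns a set
of ncRNAs, diseases and genes; direct ncRNA-disease edges appear within a
block with probability ``p_intra`` and across blocks with probability
``p_noise``; gene wiring is dense within a block.  Attributes are
block-correlated (per-block numeric means with shared noise, per-block
dominant categorical labels with a flip probability), mirroring the
network-autocorrelation assumption that nearby nodes look alike.

Also houses two hand-built fixtures: the two-cluster worked example used
throughout the prediction stage, and a small network whose single
gene-mediated meta-path yields exactly 2 sequences out of one ncRNA and 4
into one disease.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .hclus import ExtractedRelationships, MultiTypeCluster
from .hetnet import AttributeSpec, HeterogeneousNetwork, NetworkSchema

__all__ = [
    "SynthConfig",
    "GroundTruth",
    "generate_network",
    "write_ground_truth",
    "worked_example_fixture",
    "toy_sequence_fixture",
]


@dataclass
class SynthConfig:
    """Parameters of the planted-cluster generator (deterministic per seed)."""

    n_clusters: int = 3
    ncrnas_per_cluster: int = 4
    diseases_per_cluster: int = 5
    genes_per_cluster: int = 3
    n_background_genes: int = 2
    with_proteins: bool = True
    proteins_per_gene: int = 2
    p_intra: float = 0.9  # direct ncRNA-disease edge inside a planted cluster
    p_noise: float = 0.0  # direct ncRNA-disease edge across clusters
    p_gene_intra: float = 0.9  # ncRNA-gene and gene-disease wiring inside a cluster
    attr_cluster_spacing: float = 3.0
    attr_noise_sd: float = 0.5
    categorical_flip: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_intra", "p_noise", "p_gene_intra", "categorical_flip"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability, got {v}")
        for name in ("n_clusters", "ncrnas_per_cluster", "diseases_per_cluster", "genes_per_cluster"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")


@dataclass
class GroundTruth:
    """Planted structure emitted alongside the network."""

    clusters: list[MultiTypeCluster]
    positive_pairs: set[tuple[str, str]] = field(default_factory=set)

    def to_dict(self) -> dict:
        return {
            "clusters": [
                {"ncrnas": sorted(c.ncrnas), "diseases": sorted(c.diseases)}
                for c in self.clusters
            ],
            "positive_pairs": sorted(self.positive_pairs),
        }


_CATEGORIES = ["alpha", "beta", "gamma", "delta", "epsilon"]


def _schema(with_proteins: bool) -> NetworkSchema:
    node_types = {
        "ncRNA": [
            AttributeSpec("expression", "numeric"),
            AttributeSpec("biotype", "categorical"),
            AttributeSpec("marker", "categorical"),
        ],
        "disease": [
            AttributeSpec("prevalence", "numeric"),
            AttributeSpec("category", "categorical"),
            AttributeSpec("marker", "categorical"),
        ],
        "gene": [
            AttributeSpec("conservation", "numeric"),
            AttributeSpec("marker", "categorical"),
        ],
    }
    edge_types = {
        "ncRNA-disease": ("ncRNA", "disease"),
        "ncRNA-gene": ("ncRNA", "gene"),
        "gene-disease": ("gene", "disease"),
    }
    if with_proteins:
        node_types["protein"] = [
            AttributeSpec("abundance", "numeric"),
            AttributeSpec("localization", "categorical"),
            AttributeSpec("marker", "categorical"),
        ]
        edge_types["gene-protein"] = ("gene", "protein")
    return NetworkSchema(node_types=node_types, target_types=("ncRNA", "disease"), edge_types=edge_types)


def generate_network(cfg: SynthConfig) -> tuple[HeterogeneousNetwork, GroundTruth]:
    """Draw one network plus its planted ground truth, deterministically."""
    rng = np.random.default_rng(cfg.seed)
    schema = _schema(cfg.with_proteins)

    def block_numeric(cluster_idx: int) -> float:
        return float(cluster_idx * cfg.attr_cluster_spacing + rng.normal(0.0, cfg.attr_noise_sd))

    def block_categorical(cluster_idx: int) -> str:
        dominant = _CATEGORIES[cluster_idx % len(_CATEGORIES)]
        if rng.random() < cfg.categorical_flip:
            return str(rng.choice([c for c in _CATEGORIES if c != dominant]))
        return dominant

    def block_marker(cluster_idx: int) -> str:
        # per-cluster label; flips land on another cluster's label
        if cfg.n_clusters > 1 and rng.random() < cfg.categorical_flip:
            other = [f"m{c}" for c in range(cfg.n_clusters) if c != cluster_idx]
            return str(rng.choice(other))
        return f"m{cluster_idx}"

    nodes: dict[str, dict[str, dict[str, object]]] = {t: {} for t in schema.node_types}
    cluster_members: list[dict[str, list[str]]] = []
    for c in range(cfg.n_clusters):
        members = {"ncRNA": [], "disease": [], "gene": []}
        for i in range(cfg.ncrnas_per_cluster):
            nid = f"n{c}_{i}"
            nodes["ncRNA"][nid] = {
                "expression": block_numeric(c),
                "biotype": block_categorical(c),
                "marker": block_marker(c),
            }
            members["ncRNA"].append(nid)
        for i in range(cfg.diseases_per_cluster):
            did = f"d{c}_{i}"
            nodes["disease"][did] = {
                "prevalence": block_numeric(c),
                "category": block_categorical(c),
                "marker": block_marker(c),
            }
            members["disease"].append(did)
        for i in range(cfg.genes_per_cluster):
            gid = f"g{c}_{i}"
            nodes["gene"][gid] = {"conservation": block_numeric(c), "marker": block_marker(c)}
            members["gene"].append(gid)
        cluster_members.append(members)
    for i in range(cfg.n_background_genes):
        nodes["gene"][f"gbg_{i}"] = {
            "conservation": float(rng.normal(0.0, 1.0)),
            "marker": "background",
        }

    edges: dict[str, set[tuple[str, str]]] = {e: set() for e in schema.edge_types}
    positives: set[tuple[str, str]] = set()
    for c, members in enumerate(cluster_members):
        for n, d in itertools.product(members["ncRNA"], members["disease"]):
            if rng.random() < cfg.p_intra:
                edges["ncRNA-disease"].add((n, d))
                positives.add((n, d))
        for n, g in itertools.product(members["ncRNA"], members["gene"]):
            if rng.random() < cfg.p_gene_intra:
                edges["ncRNA-gene"].add((n, g))
        for g, d in itertools.product(members["gene"], members["disease"]):
            if rng.random() < cfg.p_gene_intra:
                edges["gene-disease"].add((g, d))
    # cross-cluster noise on the direct target-target links
    if cfg.p_noise > 0:
        for ci, cj in itertools.permutations(range(cfg.n_clusters), 2):
            for n in cluster_members[ci]["ncRNA"]:
                for d in cluster_members[cj]["disease"]:
                    if rng.random() < cfg.p_noise:
                        edges["ncRNA-disease"].add((n, d))
                        positives.add((n, d))

    if cfg.with_proteins:
        for c, members in enumerate(cluster_members):
            for g in members["gene"]:
                for k in range(cfg.proteins_per_gene):
                    pid = f"p_{g}_{k}"
                    nodes["protein"][pid] = {
                        "abundance": block_numeric(c),
                        "localization": block_categorical(c),
                        "marker": block_marker(c),
                    }
                    edges["gene-protein"].add((g, pid))

    net = HeterogeneousNetwork(schema=schema, nodes=nodes, edges=edges)
    truth = GroundTruth(
        clusters=[
            MultiTypeCluster(frozenset(m["ncRNA"]), frozenset(m["disease"]))
            for m in cluster_members
        ],
        positive_pairs=positives,
    )
    return net, truth


def write_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(truth.to_dict(), fh, indent=1, sort_keys=True)


# ---------------------------------------------------------------------------
# hand-built fixtures
# ---------------------------------------------------------------------------


def worked_example_fixture() -> tuple[list[MultiTypeCluster], ExtractedRelationships]:
    """The two-overlapping-cluster worked example of the prediction stage.

    C_1 = {n1, n2} x {d1, d2, d3} with retained scores 0.7, 0.8, 0.9 on the
    pairs of n1; C_2 = {n2} x {d3, d4} with one retained score 0.6 on
    (n2, d4).  The clusters overlap on (n2, d3); the new candidate pairs of
    C_1 include (n2, d2) and (n2, d3).
    """
    c1 = MultiTypeCluster(frozenset(["n1", "n2"]), frozenset(["d1", "d2", "d3"]))
    c2 = MultiTypeCluster(frozenset(["n2"]), frozenset(["d3", "d4"]))
    rel = ExtractedRelationships(
        scores={
            ("n1", "d1"): 0.7,
            ("n1", "d2"): 0.8,
            ("n1", "d3"): 0.9,
            ("n2", "d4"): 0.6,
        },
        beta=0.0,
    )
    return [c1, c2], rel


def toy_sequence_fixture() -> HeterogeneousNetwork:
    """Network whose ncRNA-gene-disease meta-path has exactly 2 sequences
    starting at ``h19`` and 4 ending at ``asthma`` (and no path joining
    them), so the pathscore is a maximum over 2 x 4 sequence comparisons."""
    schema = NetworkSchema(
        node_types={
            "ncRNA": [
                AttributeSpec("expression", "numeric"),
                AttributeSpec("biotype", "categorical"),
            ],
            "disease": [AttributeSpec("prevalence", "numeric")],
            "gene": [AttributeSpec("conservation", "numeric")],
        },
        target_types=("ncRNA", "disease"),
        edge_types={
            "ncRNA-disease": ("ncRNA", "disease"),
            "ncRNA-gene": ("ncRNA", "gene"),
            "gene-disease": ("gene", "disease"),
        },
    )
    nodes = {
        "ncRNA": {
            "h19": {"expression": 5.0, "biotype": "lncrna"},
            "n2": {"expression": 4.0, "biotype": "lncrna"},
            "n3": {"expression": 1.0, "biotype": "mirna"},
        },
        "disease": {
            "asthma": {"prevalence": 2.0},
            "d2": {"prevalence": 3.0},
        },
        "gene": {
            "g1": {"conservation": 0.9},
            "g2": {"conservation": 0.2},
            "g3": {"conservation": 0.8},
            "g4": {"conservation": 0.4},
        },
    }
    edges = {
        "ncRNA-disease": set(),
        "ncRNA-gene": {
            ("h19", "g1"),
            ("h19", "g2"),
            ("n2", "g3"),
            ("n2", "g4"),
            ("n3", "g3"),
            ("n3", "g4"),
        },
        "gene-disease": {
            ("g1", "d2"),
            ("g2", "d2"),
            ("g3", "asthma"),
            ("g4", "asthma"),
        },
    }
    return HeterogeneousNetwork(schema=schema, nodes=nodes, edges=edges)
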