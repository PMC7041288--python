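"""Data model, validation and I/O for attributed heterogeneous networks.

A heterogeneous network carries several node types, each with its own
attribute schema (numeric or categorical), and several edge types, each
joining a declared pair of node types.  Two node types are designated as
*target* types (by convention a non-coding RNA type and a disease type):
the links to be predicted run between them.  All remaining *task-relevant*
types (genes, proteins, ...) provide evidence only.

Edges are stored typed but traversed as undirected: meta-paths are node
sequences, not directed walks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd
import yaml

__all__ = [
    "AttributeSpec",
    "NetworkSchema",
    "HeterogeneousNetwork",
    "NetworkValidationError",
    "load_network",
    "load_schema",
    "write_network",
]

#: tokens treated as an explicitly missing cell in node/edge tables
MISSING_TOKENS = {"", "NA"}


class NetworkValidationError(ValueError):
    """Raised when a schema or network violates its declared structure."""


@dataclass(frozen=True)
class AttributeSpec:
    """Declaration of one node attribute: its name and kind."""

    name: str
    kind: str  # "numeric" | "categorical"

    def __post_init__(self) -> None:
        if self.kind not in ("numeric", "categorical"):
            raise NetworkValidationError(
                f"attribute {self.name!r}: kind must be 'numeric' or "
                f"'categorical', got {self.kind!r}"
            )


@dataclass
class NetworkSchema:
    """Declared structure of a heterogeneous network.

    Parameters
    ----------
    node_types
        Mapping node-type name -> ordered list of attribute declarations.
    target_types
        The two node types whose links are predicted, ordered
        (ncRNA-like type first, disease-like type second).
    edge_types
        Mapping edge-type name -> (source node type, target node type).
        The orientation is declarative only; traversal is undirected.
    """

    node_types: dict[str, list[AttributeSpec]]
    target_types: tuple[str, str]
    edge_types: dict[str, tuple[str, str]]

    def __post_init__(self) -> None:
        self.target_types = tuple(self.target_types)  # type: ignore[assignment]
        if len(self.target_types) != 2 or self.target_types[0] == self.target_types[1]:
            raise NetworkValidationError(
                f"target_types must be two distinct node types, got {self.target_types}"
            )
        for t in self.target_types:
            if t not in self.node_types:
                raise NetworkValidationError(f"target type {t!r} is not a declared node type")
        for name, (src, dst) in self.edge_types.items():
            for endpoint in (src, dst):
                if endpoint not in self.node_types:
                    raise NetworkValidationError(
                        f"edge type {name!r} endpoint {endpoint!r} is not a declared node type"
                    )
        for ntype, specs in self.node_types.items():
            names = [a.name for a in specs]
            if len(names) != len(set(names)):
                raise NetworkValidationError(f"duplicate attribute name in node type {ntype!r}")

    @property
    def task_relevant_types(self) -> set[str]:
        return set(self.node_types) - set(self.target_types)

    def attributes(self, node_type: str) -> list[AttributeSpec]:
        return self.node_types[node_type]

    def copy(self) -> "NetworkSchema":
        return NetworkSchema(
            node_types={t: list(a) for t, a in self.node_types.items()},
            target_types=self.target_types,
            edge_types=dict(self.edge_types),
        )

    def to_dict(self) -> dict:
        return {
            "node_types": {
                t: {"attributes": [{"name": a.name, "kind": a.kind} for a in specs]}
                for t, specs in self.node_types.items()
            },
            "target_types": list(self.target_types),
            "edge_types": [
                {"name": n, "source": s, "target": d} for n, (s, d) in self.edge_types.items()
            ],
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "NetworkSchema":
        node_types = {
            t: [AttributeSpec(a["name"], a["kind"]) for a in spec.get("attributes", [])]
            for t, spec in d["node_types"].items()
        }
        edge_types = {e["name"]: (e["source"], e["target"]) for e in d["edge_types"]}
        return cls(node_types=node_types, target_types=tuple(d["target_types"]), edge_types=edge_types)


@dataclass
class HeterogeneousNetwork:
    """A validated attributed heterogeneous network.

    ``nodes[node_type][node_id]`` is the attribute record of one node
    (missing values stored as ``None``); ``edges[edge_type]`` is a set of
    ``(source_id, target_id)`` pairs oriented as declared.  Edge attribute
    records, when present in the input tables, are preserved in
    ``edge_attrs`` but play no role in any computation.
    """

    schema: NetworkSchema
    nodes: dict[str, dict[str, dict[str, object]]]
    edges: dict[str, set[tuple[str, str]]]
    edge_attrs: dict[str, dict[tuple[str, str], dict[str, object]]] = field(default_factory=dict)
    _graph: nx.MultiGraph | None = field(default=None, repr=False, compare=False)

    # -- construction -------------------------------------------------

    def __post_init__(self) -> None:
        for ntype in self.schema.node_types:
            self.nodes.setdefault(ntype, {})
        for etype in self.schema.edge_types:
            self.edges.setdefault(etype, set())
        self.validate()

    def validate(self) -> None:
        for etype, pairs in self.edges.items():
            if etype not in self.schema.edge_types:
                raise NetworkValidationError(f"undeclared edge type {etype!r}")
            src_t, dst_t = self.schema.edge_types[etype]
            for s, d in pairs:
                if s not in self.nodes.get(src_t, {}):
                    raise NetworkValidationError(
                        f"edge type {etype!r}: unknown {src_t} node {s!r}"
                    )
                if d not in self.nodes.get(dst_t, {}):
                    raise NetworkValidationError(
                        f"edge type {etype!r}: unknown {dst_t} node {d!r}"
                    )
        for ntype, table in self.nodes.items():
            declared = {a.name for a in self.schema.attributes(ntype)}
            for nid, rec in table.items():
                unknown = set(rec) - declared
                if unknown:
                    raise NetworkValidationError(
                        f"node {nid!r} of type {ntype!r} carries undeclared attributes {unknown}"
                    )

    # -- graph views ---------------------------------------------------

    @property
    def graph(self) -> nx.MultiGraph:
        """Undirected multigraph view; nodes keyed ``(type, id)``, edge key = edge type."""
        if self._graph is None:
            g = nx.MultiGraph()
            for ntype, table in self.nodes.items():
                g.add_nodes_from((ntype, nid) for nid in table)
            for etype, pairs in self.edges.items():
                src_t, dst_t = self.schema.edge_types[etype]
                for s, d in pairs:
                    g.add_edge((src_t, s), (dst_t, d), key=etype)
            self._graph = g
        return self._graph

    def _invalidate(self) -> None:
        self._graph = None

    def neighbors(self, node: tuple[str, str], via: str | None = None) -> set[tuple[str, str]]:
        """All nodes adjacent to ``node`` through any (or the named) edge type."""
        if node not in self.graph:
            raise KeyError(f"unknown node {node!r}")
        if via is None:
            return set(self.graph[node])
        if via not in self.schema.edge_types:
            raise KeyError(f"unknown edge type {via!r}")
        return {
            nbr
            for nbr, keyed in self.graph[node].items()
            if via in keyed
        }

    # -- target pairs --------------------------------------------------

    def target_edge_types(self) -> list[str]:
        """Edge types whose endpoints are exactly the two target types."""
        t1, t2 = self.schema.target_types
        return sorted(
            name
            for name, (s, d) in self.schema.edge_types.items()
            if {s, d} == {t1, t2}
        )

    def known_target_pairs(self) -> set[tuple[str, str]]:
        """Directly linked target pairs, oriented (ncRNA-type id, disease-type id)."""
        t1, _ = self.schema.target_types
        out: set[tuple[str, str]] = set()
        for etype in self.target_edge_types():
            src_t, _dst_t = self.schema.edge_types[etype]
            for s, d in self.edges[etype]:
                out.add((s, d) if src_t == t1 else (d, s))
        return out

    def target_nodes(self) -> tuple[list[str], list[str]]:
        t1, t2 = self.schema.target_types
        return sorted(self.nodes[t1]), sorted(self.nodes[t2])

    # -- mutation helpers (evaluation folds) ---------------------------

    def copy(self) -> "HeterogeneousNetwork":
        return HeterogeneousNetwork(
            schema=self.schema.copy(),
            nodes={t: {i: dict(r) for i, r in tab.items()} for t, tab in self.nodes.items()},
            edges={e: set(p) for e, p in self.edges.items()},
            edge_attrs={e: dict(a) for e, a in self.edge_attrs.items()},
        )

    def remove_target_edges(self, pairs: Iterable[tuple[str, str]]) -> None:
        """Delete the direct target-target edges listed (nodes are retained)."""
        drop = set(pairs)
        t1, _ = self.schema.target_types
        for etype in self.target_edge_types():
            src_t, _ = self.schema.edge_types[etype]
            kept = set()
            for s, d in self.edges[etype]:
                pair = (s, d) if src_t == t1 else (d, s)
                if pair not in drop:
                    kept.add((s, d))
            self.edges[etype] = kept
        self._invalidate()


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def load_schema(schema_file: str | Path) -> NetworkSchema:
    """Parse a YAML/JSON schema declaration into a :class:`NetworkSchema`."""
    with open(schema_file, "r", encoding="utf-8") as fh:
        return NetworkSchema.from_dict(yaml.safe_load(fh))


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def _read_table(path: Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep=_sep_for(path), dtype=str, keep_default_na=False)
    return df


def _parse_cell(token: str, kind: str, where: str):
    if token in MISSING_TOKENS:
        return None
    if kind == "numeric":
        try:
            v = float(token)
        except ValueError:
            raise NetworkValidationError(f"{where}: non-numeric token {token!r} in numeric column")
        if v != v or v in (float("inf"), float("-inf")):
            raise NetworkValidationError(f"{where}: non-finite value {token!r}")
        return v
    return token


def load_network(
    schema_file: str | Path,
    node_tables: Mapping[str, str | Path],
    edge_tables: Mapping[str, str | Path],
) -> HeterogeneousNetwork:
    """Load and validate a network from a schema file plus delimited tables.

    Node tables: column 1 = node ID, remaining columns = declared attributes.
    Edge tables: columns 1-2 = source and target IDs; any further columns are
    preserved as inert edge attributes.  Empty cells and the literal ``NA``
    are recorded as missing; duplicate edges collapse to one.
    """
    schema = load_schema(schema_file)
    missing_types = set(schema.node_types) - set(node_tables)
    if missing_types:
        raise NetworkValidationError(f"no node table supplied for types {sorted(missing_types)}")

    nodes: dict[str, dict[str, dict[str, object]]] = {}
    for ntype, path in node_tables.items():
        if ntype not in schema.node_types:
            raise NetworkValidationError(f"node table for undeclared type {ntype!r}")
        path = Path(path)
        df = _read_table(path)
        specs = schema.attributes(ntype)
        declared = [a.name for a in specs]
        absent = set(declared) - set(df.columns[1:])
        if absent:
            raise NetworkValidationError(f"{path}: missing declared columns {sorted(absent)}")
        table: dict[str, dict[str, object]] = {}
        for row_no, row in enumerate(df.itertuples(index=False, name=None), start=2):
            rec = dict(zip(df.columns, row))
            nid = str(row[0])
            if nid in table:
                raise NetworkValidationError(f"{path}:{row_no}: duplicate node ID {nid!r}")
            table[nid] = {
                a.name: _parse_cell(str(rec[a.name]), a.kind, f"{path}:{row_no}")
                for a in specs
            }
        nodes[ntype] = table

    edges: dict[str, set[tuple[str, str]]] = {}
    edge_attrs: dict[str, dict[tuple[str, str], dict[str, object]]] = {}
    for etype, path in edge_tables.items():
        if etype not in schema.edge_types:
            raise NetworkValidationError(f"edge table for undeclared edge type {etype!r}")
        path = Path(path)
        df = _read_table(path)
        src_t, dst_t = schema.edge_types[etype]
        pairs: set[tuple[str, str]] = set()
        attrs: dict[tuple[str, str], dict[str, object]] = {}
        extra_cols = list(df.columns[2:])
        for row_no, row in enumerate(df.itertuples(index=False, name=None), start=2):
            s, d = str(row[0]), str(row[1])
            if s not in nodes.get(src_t, {}):
                raise NetworkValidationError(
                    f"{path}:{row_no}: unknown {src_t} node {s!r} referenced by edge"
                )
            if d not in nodes.get(dst_t, {}):
                raise NetworkValidationError(
                    f"{path}:{row_no}: unknown {dst_t} node {d!r} referenced by edge"
                )
            pairs.add((s, d))
            if extra_cols:
                attrs[(s, d)] = {
                    c: (None if str(v) in MISSING_TOKENS else str(v))
                    for c, v in zip(extra_cols, row[2:])
                }
        edges[etype] = pairs
        if attrs:
            edge_attrs[etype] = attrs

    return HeterogeneousNetwork(schema=schema, nodes=nodes, edges=edges, edge_attrs=edge_attrs)


def _fmt(value: object) -> str:
    if value is None:
        return ""
    if isinstance(value, float) and value == int(value):
        return str(int(value))
    return str(value)


def write_network(net: HeterogeneousNetwork, outdir: str | Path) -> dict[str, Path]:
    """Write ``schema.yaml`` plus one TSV per node type and edge type.

    Returns the mapping of logical names to written paths; the output can be
    reloaded with :func:`load_network` to reproduce the network exactly.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    schema_path = outdir / "schema.yaml"
    with open(schema_path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(net.schema.to_dict(), fh, sort_keys=False)
    paths["schema"] = schema_path

    for ntype in sorted(net.nodes):
        specs = net.schema.attributes(ntype)
        rows = [
            [nid] + [_fmt(net.nodes[ntype][nid].get(a.name)) for a in specs]
            for nid in sorted(net.nodes[ntype])
        ]
        df = pd.DataFrame(rows, columns=["id"] + [a.name for a in specs])
        p = outdir / f"nodes_{ntype}.tsv"
        df.to_csv(p, sep="\t", index=False)
        paths[f"nodes:{ntype}"] = p

    for etype in sorted(net.edges):
        df = pd.DataFrame(sorted(net.edges[etype]), columns=["source", "target"])
        p = outdir / f"edges_{etype}.tsv"
        df.to_csv(p, sep="\t", index=False)
        paths[f"edges:{etype}"] = p

    return paths
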