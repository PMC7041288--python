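"""Stage 1 — degree-of-certainty scores for target pairs via meta-paths.

A *meta-path* is an ordered sequence of node types (joined by declared edge
types) running from the ncRNA-like target type to the disease-like target
type.  Its instances are concrete node sequences ("path sequences").  The
score s(n, d) of a target pair is the fuzzy-OR (maximum) over meta-paths of
a per-meta-path ``pathscore``:

* if some sequence of the meta-path runs from n to d, the pair is directly
  connected along it and the pathscore is 1;
* otherwise the pathscore is the maximum attribute-profile similarity
  between the sequences starting at n and those ending at d, where sequence
  similarity is the mean over all node attributes along the meta-path of a
  per-attribute similarity (range-normalised distance for numeric
  attributes, identity for categorical ones).

Node types that sit on no meta-path still contribute: their attributes are
aggregated (mean for numeric, mode for categorical) onto adjacent on-path
nodes up to a configurable propagation depth before scoring.
"""

from __future__ import annotations

import itertools
import warnings
from collections import Counter, deque
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .hetnet import AttributeSpec, HeterogeneousNetwork

__all__ = [
    "MetaPath",
    "AttributeStats",
    "ScoredPairMatrix",
    "SequenceStore",
    "enumerate_metapaths",
    "enrich_attributes",
    "attribute_similarity",
    "sequence_similarity",
    "materialize_sequences",
    "pathscore",
    "score_all_pairs",
]


@dataclass(frozen=True)
class MetaPath:
    """An ordered walk over the schema from one target type to the other."""

    node_types: tuple[str, ...]
    edge_types: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.node_types) != len(self.edge_types) + 1 or not self.edge_types:
            raise ValueError("meta-path needs k node types joined by k-1 >= 1 edge types")

    def __len__(self) -> int:  # number of edges
        return len(self.edge_types)

    def __str__(self) -> str:
        return ".".join(self.node_types)


def enumerate_metapaths(net: HeterogeneousNetwork, max_len: int = 3) -> list[MetaPath]:
    """All meta-paths between the two target types with at most ``max_len``
    edges and no repeated node type, ordered shortest first then
    lexicographically by node-type and edge-type names."""
    if max_len < 1:
        raise ValueError("max_len must be >= 1")
    schema = net.schema
    start, goal = schema.target_types
    # adjacency at the type level: type -> [(edge_type, other_type)]
    adj: dict[str, list[tuple[str, str]]] = {t: [] for t in schema.node_types}
    for etype, (s, d) in schema.edge_types.items():
        adj[s].append((etype, d))
        if s != d:
            adj[d].append((etype, s))

    found: list[MetaPath] = []

    def walk(types: list[str], edges: list[str]) -> None:
        here = types[-1]
        if here == goal and edges:
            found.append(MetaPath(tuple(types), tuple(edges)))
            return  # type repetition forbidden, so no extension past the goal
        if len(edges) == max_len:
            return
        for etype, nxt in adj[here]:
            if nxt in types:
                continue
            walk(types + [nxt], edges + [etype])

    walk([start], [])
    found.sort(key=lambda mp: (len(mp), mp.node_types, mp.edge_types))
    if not found:
        warnings.warn("no meta-path connects the target types", stacklevel=2)
    return found


# ---------------------------------------------------------------------------
# off-path attribute propagation
# ---------------------------------------------------------------------------


def _aggregate(values: list, kind: str):
    present = [v for v in values if v is not None]
    if not present:
        return None
    if kind == "numeric":
        return sum(present) / len(present)
    counts = Counter(present)
    top = max(counts.values())
    return min(v for v, c in counts.items() if c == top)  # lexicographic tie-break


def enrich_attributes(
    net: HeterogeneousNetwork, metapaths: list[MetaPath], depth: int = 2
) -> HeterogeneousNetwork:
    """Fold off-path node attributes onto adjacent on-path nodes.

    For every node of a type that appears on at least one meta-path, the
    off-path nodes reachable within ``depth`` hops through off-path nodes
    only are collected; their numeric attributes are averaged and their
    categorical attributes summarised by the mode (ties -> lexicographically
    smallest).  The aggregates are appended as new attributes named
    ``{off_type}.{attribute}@d{depth}``.  ``depth=0`` is the identity.
    """
    if depth < 0:
        raise ValueError("depth must be >= 0")
    if depth == 0:
        return net

    on_path = set(itertools.chain.from_iterable(mp.node_types for mp in metapaths))
    off_path = set(net.schema.node_types) - on_path
    if not off_path:
        return net

    out = net.copy()
    graph = net.graph

    # reachability at the type level decides which new attributes each
    # on-path type is declared to carry
    type_adj: dict[str, set[str]] = {t: set() for t in net.schema.node_types}
    for s, d in net.schema.edge_types.values():
        type_adj[s].add(d)
        type_adj[d].add(s)

    def reachable_off_types(t: str) -> list[str]:
        seen: set[str] = set()
        frontier = {t}
        for _ in range(depth):
            frontier = {
                nxt
                for cur in frontier
                for nxt in type_adj[cur]
                if nxt in off_path and nxt not in seen
            }
            seen |= frontier
        return sorted(seen)

    new_specs: dict[str, list[tuple[str, AttributeSpec, str]]] = {}
    for t in sorted(on_path & set(net.schema.node_types)):
        specs = []
        for off_t in reachable_off_types(t):
            for a in net.schema.attributes(off_t):
                specs.append((off_t, a, f"{off_t}.{a.name}@d{depth}"))
        new_specs[t] = specs
        out.schema.node_types[t] = out.schema.node_types[t] + [
            AttributeSpec(new_name, a.kind) for _off, a, new_name in specs
        ]

    for t, specs in new_specs.items():
        if not specs:
            continue
        for nid in net.nodes[t]:
            # BFS through off-path nodes only, up to `depth` hops
            reached: dict[str, list[str]] = {}
            seen = {(t, nid)}
            frontier: deque[tuple[tuple[str, str], int]] = deque([((t, nid), 0)])
            while frontier:
                node, dist = frontier.popleft()
                if dist == depth:
                    continue
                for nbr in graph[node]:
                    if nbr in seen:
                        continue
                    nbr_t, nbr_id = nbr
                    if nbr_t not in off_path:
                        continue
                    seen.add(nbr)
                    reached.setdefault(nbr_t, []).append(nbr_id)
                    frontier.append((nbr, dist + 1))
            rec = out.nodes[t][nid]
            for off_t, a, new_name in specs:
                vals = [net.nodes[off_t][i].get(a.name) for i in reached.get(off_t, [])]
                rec[new_name] = _aggregate(vals, a.kind)

    out._invalidate()
    return out


# ---------------------------------------------------------------------------
# similarity
# ---------------------------------------------------------------------------


@dataclass
class AttributeStats:
    """Global per-(node type, numeric attribute) min/max for normalisation."""

    min_max: dict[tuple[str, str], tuple[float, float]]

    @classmethod
    def from_network(cls, net: HeterogeneousNetwork) -> "AttributeStats":
        mm: dict[tuple[str, str], tuple[float, float]] = {}
        for ntype, table in net.nodes.items():
            for a in net.schema.attributes(ntype):
                if a.kind != "numeric":
                    continue
                vals = [rec.get(a.name) for rec in table.values()]
                vals = [v for v in vals if v is not None]
                if vals:
                    mm[(ntype, a.name)] = (min(vals), max(vals))
        return cls(mm)


def attribute_similarity(
    kind: str,
    v1,
    v2,
    min_max: tuple[float, float] | None = None,
) -> float | None:
    """Similarity of two values of one attribute, in [0, 1].

    Numeric: ``1 - |v1 - v2| / (max - min)`` with the global attribute range;
    a constant attribute (max == min) compares as 1.  Categorical: exact
    identity.  Returns ``None`` when either value is missing (the caller
    drops the attribute from both numerator and denominator).
    """
    if v1 is None or v2 is None:
        return None
    if kind == "numeric":
        if min_max is None:
            raise ValueError("numeric attribute requires min/max stats")
        lo, hi = min_max
        if hi == lo:
            return 1.0
        return max(0.0, 1.0 - abs(v1 - v2) / (hi - lo))
    return 1.0 if v1 == v2 else 0.0


def sequence_similarity(
    net: HeterogeneousNetwork,
    mp: MetaPath,
    seq1: tuple[str, ...],
    seq2: tuple[str, ...],
    stats: AttributeStats,
) -> float:
    """Mean per-attribute similarity over all node positions of the meta-path.

    Position i of ``seq1`` is compared with position i of ``seq2`` on every
    declared attribute of that position's node type; attribute pairs with a
    missing value are excluded from both numerator and denominator.  If no
    attribute pair is comparable the similarity is 0 (with a warning).
    """
    if len(seq1) != len(mp.node_types) or len(seq2) != len(mp.node_types):
        raise ValueError("sequences must instantiate the meta-path")
    total = 0.0
    compared = 0
    declared = 0
    for pos, ntype in enumerate(mp.node_types):
        r1 = net.nodes[ntype][seq1[pos]]
        r2 = net.nodes[ntype][seq2[pos]]
        for a in net.schema.attributes(ntype):
            declared += 1
            s = attribute_similarity(
                a.kind, r1.get(a.name), r2.get(a.name), stats.min_max.get((ntype, a.name))
            )
            if s is not None:
                total += s
                compared += 1
    if declared == 0 or compared == 0:
        warnings.warn("no comparable attributes along meta-path; similarity set to 0", stacklevel=2)
        return 0.0
    return total / compared


# ---------------------------------------------------------------------------
# sequence materialization and scoring
# ---------------------------------------------------------------------------


@dataclass
class SequenceStore:
    """Concrete sequences of one meta-path, indexed by first and last node."""

    metapath: MetaPath
    by_start: dict[str, list[tuple[str, ...]]] = field(default_factory=dict)
    by_end: dict[str, list[tuple[str, ...]]] = field(default_factory=dict)
    truncated: bool = False


def materialize_sequences(
    net: HeterogeneousNetwork, mp: MetaPath, seq_cap: int = 1000
) -> SequenceStore:
    """Enumerate the node sequences instantiating ``mp``.

    Sequences are generated in lexicographic node-ID order and capped at
    ``seq_cap`` per starting node and per ending node (deterministic
    truncation, flagged on the store).
    """
    store = SequenceStore(mp)
    graph = net.graph
    start_type = mp.node_types[0]

    def extend(seq: list[str], pos: int):
        if pos == len(mp.node_types) - 1:
            yield tuple(seq)
            return
        here = (mp.node_types[pos], seq[-1])
        want_t = mp.node_types[pos + 1]
        want_e = mp.edge_types[pos]
        if here not in graph:
            return
        nbrs = sorted(
            nid
            for (t, nid), keyed in graph[here].items()
            if t == want_t and want_e in keyed
        )
        for nid in nbrs:
            yield from extend(seq + [nid], pos + 1)

    for start in sorted(net.nodes.get(start_type, {})):
        bucket: list[tuple[str, ...]] = []
        for seq in extend([start], 0):
            if len(bucket) >= seq_cap:
                store.truncated = True
                break
            bucket.append(seq)
        if bucket:
            store.by_start[start] = bucket

    for seqs in store.by_start.values():
        for seq in seqs:
            store.by_end.setdefault(seq[-1], []).append(seq)
    for end, seqs in store.by_end.items():
        seqs.sort()
        if len(seqs) > seq_cap:
            store.truncated = True
            store.by_end[end] = seqs[:seq_cap]
    if store.truncated:
        warnings.warn(
            f"sequence cap {seq_cap} reached for meta-path {mp}; results deterministically truncated",
            stacklevel=2,
        )
    return store


def pathscore(
    net: HeterogeneousNetwork,
    mp: MetaPath,
    n: str,
    d: str,
    store: SequenceStore,
    stats: AttributeStats,
) -> float:
    """Degree of certainty of pair (n, d) along one meta-path.

    1 if some sequence of the meta-path runs from n to d; otherwise the
    maximum similarity between sequences starting at n and sequences ending
    at d; 0 when either set is empty.
    """
    starts = store.by_start.get(n, [])
    ends = store.by_end.get(d, [])
    if not starts or not ends:
        return 0.0
    for seq in starts:
        if seq[-1] == d:
            return 1.0
    return max(
        sequence_similarity(net, mp, s1, s2, stats) for s1 in starts for s2 in ends
    )


@dataclass
class ScoredPairMatrix:
    """Degree-of-certainty s(n, d) in [0, 1] for every target pair.

    Pairs with no meta-path evidence are implicit zeros; ``provenance``
    records the best-scoring meta-path per explicitly scored pair.
    """

    scores: dict[tuple[str, str], float]
    ncrnas: list[str]
    diseases: list[str]
    provenance: dict[tuple[str, str], MetaPath] = field(default_factory=dict)

    def get(self, pair: tuple[str, str]) -> float:
        return self.scores.get(pair, 0.0)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "ncrna_id": n,
                "disease_id": d,
                "score": self.scores.get((n, d), 0.0),
                "best_metapath": str(self.provenance[(n, d)]) if (n, d) in self.provenance else "",
            }
            for n in sorted(self.ncrnas)
            for d in sorted(self.diseases)
        ]
        return pd.DataFrame(rows, columns=["ncrna_id", "disease_id", "score", "best_metapath"])

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def score_all_pairs(
    net: HeterogeneousNetwork,
    max_len: int = 3,
    depth: int = 2,
    seq_cap: int = 1000,
) -> ScoredPairMatrix:
    """Score every (ncRNA, disease) pair: fuzzy-OR of pathscores (Stage 1).

    Directly linked pairs always score exactly 1; pairs with no meta-path
    evidence score 0.
    """
    mps = enumerate_metapaths(net, max_len=max_len)
    ncrnas, diseases = net.target_nodes()
    matrix = ScoredPairMatrix(scores={}, ncrnas=ncrnas, diseases=diseases)
    if not mps:
        return matrix
    enriched = enrich_attributes(net, mps, depth=depth)
    stats = AttributeStats.from_network(enriched)
    for mp in mps:
        store = materialize_sequences(enriched, mp, seq_cap=seq_cap)
        for n in ncrnas:
            if n not in store.by_start:
                continue
            for d in diseases:
                if d not in store.by_end:
                    continue
                s = pathscore(enriched, mp, n, d, store, stats)
                if s > matrix.scores.get((n, d), 0.0):
                    matrix.scores[(n, d)] = s
                    matrix.provenance[(n, d)] = mp
    return matrix
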