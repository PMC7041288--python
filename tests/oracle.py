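"""Independent brute-force oracle for the pair-scoring stage.

Re-derives the degree of certainty of every target pair from first
principles: enumerate every meta-path over the schema (no repeated node
type, bounded edge count), instantiate every node sequence by exhaustive
product-and-check over the edge sets, evaluate sequence similarity naively
and take the max-of-max composition.  Shares no code with
``hetlink.metapath``; intended only for small networks without off-path
node types (so attribute propagation is a no-op on both sides).
"""

from __future__ import annotations

import itertools


def _type_adjacency(schema):
    adj = {}
    for etype, (s, d) in schema.edge_types.items():
        adj.setdefault(s, []).append((etype, d))
        if s != d:
            adj.setdefault(d, []).append((etype, s))
    return adj


def enumerate_type_paths(schema, max_len):
    """All (node-type tuple, edge-type tuple) walks between the targets."""
    start, goal = schema.target_types
    adj = _type_adjacency(schema)
    out = []
    stack = [([start], [])]
    while stack:
        types, etypes = stack.pop()
        if types[-1] == goal and etypes:
            out.append((tuple(types), tuple(etypes)))
            continue
        if len(etypes) >= max_len:
            continue
        for etype, nxt in adj.get(types[-1], []):
            if nxt not in types:
                stack.append((types + [nxt], etypes + [etype]))
    return out


def _undirected(net, etype):
    pairs = set()
    for s, d in net.edges.get(etype, set()):
        pairs.add((s, d))
        pairs.add((d, s))
    return pairs


def all_sequences(net, type_path, edge_path):
    """Every concrete node sequence instantiating the typed walk."""
    pools = [sorted(net.nodes.get(t, {})) for t in type_path]
    links = []
    for i, etype in enumerate(edge_path):
        src_t, _ = net.schema.edge_types[etype]
        und = _undirected(net, etype)
        # orient membership test to (type_path[i], type_path[i+1]) order
        links.append(und)
    seqs = []
    for combo in itertools.product(*pools):
        ok = all(
            (combo[i], combo[i + 1]) in links[i] for i in range(len(edge_path))
        )
        if ok:
            seqs.append(combo)
    return seqs


def _minmax(net):
    mm = {}
    for ntype, table in net.nodes.items():
        for spec in net.schema.attributes(ntype):
            if spec.kind != "numeric":
                continue
            vals = [r.get(spec.name) for r in table.values() if r.get(spec.name) is not None]
            if vals:
                mm[(ntype, spec.name)] = (min(vals), max(vals))
    return mm


def naive_similarity(net, type_path, s1, s2, mm):
    num = 0.0
    cnt = 0
    for pos, ntype in enumerate(type_path):
        r1 = net.nodes[ntype][s1[pos]]
        r2 = net.nodes[ntype][s2[pos]]
        for spec in net.schema.attributes(ntype):
            v1, v2 = r1.get(spec.name), r2.get(spec.name)
            if v1 is None or v2 is None:
                continue
            if spec.kind == "numeric":
                lo, hi = mm[(ntype, spec.name)]
                s = 1.0 if hi == lo else max(0.0, 1.0 - abs(v1 - v2) / (hi - lo))
            else:
                s = 1.0 if v1 == v2 else 0.0
            num += s
            cnt += 1
    return num / cnt if cnt else 0.0


def brute_force_scores(net, max_len=3):
    """dict (ncRNA id, disease id) -> s(n, d), zeros omitted."""
    mm = _minmax(net)
    t_n, t_d = net.schema.target_types
    scores = {}
    for type_path, edge_path in enumerate_type_paths(net.schema, max_len):
        seqs = all_sequences(net, type_path, edge_path)
        by_start = {}
        by_end = {}
        for s in seqs:
            by_start.setdefault(s[0], []).append(s)
            by_end.setdefault(s[-1], []).append(s)
        for n in net.nodes.get(t_n, {}):
            for d in net.nodes.get(t_d, {}):
                starts = by_start.get(n, [])
                ends = by_end.get(d, [])
                if not starts or not ends:
                    continue
                if any(s[-1] == d for s in starts):
                    ps = 1.0
                else:
                    ps = max(
                        naive_similarity(net, type_path, a, b, mm)
                        for a in starts
                        for b in ends
                    )
                if ps > scores.get((n, d), 0.0):
                    scores[(n, d)] = ps
    return scores
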