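"""Stage 2 — hierarchy of overlapping multi-type clusters.

Starting from the scored target pairs, the first hierarchy level is built
in three steps: (i) *filtering* keeps the pairs with score >= beta;
(ii) *initialization* turns each retained pair into a 1x1 biclique;
(iii) *merging* greedily fuses clusters, highest-cohesiveness first, as
long as the fused cluster is still a biclique over the retained pairs
(every ncRNA-disease pair inside it retained).  Further levels repeat the
greedy merge with the biclique constraint replaced by a cohesiveness floor
alpha; each merge pass yields one level, and the process stops when no
merge is possible.

Cohesiveness h(C) is the sum of retained pair scores inside the cluster
divided by |ncrnas| * |diseases| (all possible pairs); absent pairs
contribute 0 to the numerator but still count in the denominator.
"""

from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .metapath import ScoredPairMatrix

__all__ = [
    "MultiTypeCluster",
    "ExtractedRelationships",
    "ClusterHierarchy",
    "filter_pairs",
    "cohesiveness",
    "cluster_sort_key",
    "init_bicliques",
    "merge_bicliques",
    "merge_level",
    "build_hierarchy",
]


@dataclass(frozen=True)
class MultiTypeCluster:
    """A set of ncRNAs plus a set of diseases; clusters may overlap."""

    ncrnas: frozenset[str]
    diseases: frozenset[str]

    def __post_init__(self) -> None:
        if not self.ncrnas or not self.diseases:
            raise ValueError("cluster needs at least one ncRNA and one disease")

    @property
    def pairs(self) -> list[tuple[str, str]]:
        """All possible (ncRNA, disease) pairs over the member sets."""
        return list(itertools.product(sorted(self.ncrnas), sorted(self.diseases)))

    @property
    def n_pairs(self) -> int:
        return len(self.ncrnas) * len(self.diseases)

    def union(self, other: "MultiTypeCluster") -> "MultiTypeCluster":
        return MultiTypeCluster(self.ncrnas | other.ncrnas, self.diseases | other.diseases)

    def contains(self, other: "MultiTypeCluster") -> bool:
        return other.ncrnas <= self.ncrnas and other.diseases <= self.diseases

    def members_key(self) -> tuple[tuple[str, ...], tuple[str, ...]]:
        return (tuple(sorted(self.ncrnas)), tuple(sorted(self.diseases)))


@dataclass
class ExtractedRelationships:
    """The pairs retained by the beta filter, with their scores."""

    scores: dict[tuple[str, str], float]
    beta: float

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return pair in self.scores

    def get(self, pair: tuple[str, str]) -> float:
        return self.scores.get(pair, 0.0)

    def __len__(self) -> int:
        return len(self.scores)


def filter_pairs(scores: ScoredPairMatrix, beta: float) -> ExtractedRelationships:
    """Keep exactly the target pairs whose score is >= beta."""
    if not 0.0 <= beta <= 1.0:
        raise ValueError("beta must be in [0, 1]")
    kept = {p: s for p, s in scores.scores.items() if s >= beta}
    if not kept:
        warnings.warn("beta filter retained no pairs; clustering will be empty", stacklevel=2)
    return ExtractedRelationships(scores=kept, beta=beta)


def cohesiveness(cluster: MultiTypeCluster, rel: ExtractedRelationships) -> float:
    """Average retained score over all possible pairs of the cluster."""
    total = sum(rel.get(p) for p in itertools.product(cluster.ncrnas, cluster.diseases))
    return total / cluster.n_pairs


def cluster_sort_key(cluster: MultiTypeCluster, rel: ExtractedRelationships):
    """Total-order key: higher cohesiveness first, then fewer pairs, then
    lexicographically smallest member IDs.  Deterministic refinement of the
    strict order 'h(C') > h(C'')'."""
    return (-cohesiveness(cluster, rel), cluster.n_pairs, cluster.members_key())


def init_bicliques(rel: ExtractedRelationships) -> list[MultiTypeCluster]:
    """One 1x1 cluster per retained pair, sorted by the cluster order."""
    clusters = [
        MultiTypeCluster(frozenset([n]), frozenset([d])) for (n, d) in rel.scores
    ]
    clusters.sort(key=lambda c: cluster_sort_key(c, rel))
    return clusters


def _is_biclique(cluster: MultiTypeCluster, rel: ExtractedRelationships) -> bool:
    return all(
        p in rel for p in itertools.product(cluster.ncrnas, cluster.diseases)
    )


def _dedupe(clusters: list[MultiTypeCluster]) -> list[MultiTypeCluster]:
    seen: set = set()
    out = []
    for c in clusters:
        k = c.members_key()
        if k not in seen:
            seen.add(k)
            out.append(c)
    return out


def _greedy_pass(
    clusters: list[MultiTypeCluster],
    rel: ExtractedRelationships,
    valid,
    single_pass: bool,
) -> tuple[list[MultiTypeCluster], int]:
    """Greedy cohesiveness-ordered merging.

    Scan the sorted list; merge each cluster with the first later cluster
    whose union passes ``valid``.  With ``single_pass=False`` the list is
    re-sorted after every merge and scanning restarts until a full pass
    makes no merge (level-1 fixpoint).  With ``single_pass=True`` each
    cluster merges at most once and one scan defines one level.
    """
    merges = 0
    current = sorted(_dedupe(clusters), key=lambda c: cluster_sort_key(c, rel))
    if single_pass:
        consumed: set[int] = set()
        result: list[MultiTypeCluster] = []
        for i, a in enumerate(current):
            if i in consumed:
                continue
            partner = None
            for j in range(i + 1, len(current)):
                if j in consumed:
                    continue
                cand = a.union(current[j])
                if valid(cand):
                    partner = j
                    merged = cand
                    break
            if partner is not None:
                consumed.update((i, partner))
                result.append(merged)
                merges += 1
            else:
                result.append(a)
        result = _dedupe(sorted(result, key=lambda c: cluster_sort_key(c, rel)))
        return result, merges

    changed = True
    while changed:
        changed = False
        for i, a in enumerate(current):
            hit = None
            for j in range(i + 1, len(current)):
                cand = a.union(current[j])
                if valid(cand):
                    hit = (j, cand)
                    break
            if hit is not None:
                j, merged = hit
                rest = [c for k, c in enumerate(current) if k not in (i, j)]
                current = _dedupe(
                    sorted(rest + [merged], key=lambda c: cluster_sort_key(c, rel))
                )
                merges += 1
                changed = True
                break  # re-sorted; restart the scan
    return current, merges


def merge_bicliques(
    clusters: list[MultiTypeCluster], rel: ExtractedRelationships
) -> list[MultiTypeCluster]:
    """Level-1 construction: greedy merging to a fixpoint under the biclique
    constraint (every pair of the union retained, i.e. scored >= beta)."""
    merged, _ = _greedy_pass(clusters, rel, lambda c: _is_biclique(c, rel), single_pass=False)
    return merged


def merge_level(
    prev: list[MultiTypeCluster], rel: ExtractedRelationships, alpha: float
) -> list[MultiTypeCluster] | None:
    """One greedy merge pass with validity h(union) > alpha.

    Returns the next level, or ``None`` when no merge occurred (the
    hierarchy ends at ``prev``).  Clusters that find no partner carry over
    unchanged.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must be in [0, 1]")
    nxt, merges = _greedy_pass(
        prev, rel, lambda c: cohesiveness(c, rel) > alpha, single_pass=True
    )
    if merges == 0:
        return None
    return nxt


@dataclass
class ClusterHierarchy:
    """Ordered levels [L_1, ..., L_k] of overlapping multi-type clusters."""

    levels: list[list[MultiTypeCluster]]
    rel: ExtractedRelationships
    alpha: float
    beta: float

    @property
    def depth(self) -> int:
        return len(self.levels)

    def level(self, w: int) -> list[MultiTypeCluster]:
        """1-based access to level L_w."""
        if not 1 <= w <= self.depth:
            raise IndexError(f"level {w} outside [1, {self.depth}]")
        return self.levels[w - 1]

    def to_frames(self) -> dict[int, pd.DataFrame]:
        frames = {}
        for w, level in enumerate(self.levels, start=1):
            rows = []
            for ci, c in enumerate(level):
                for n in sorted(c.ncrnas):
                    rows.append({"cluster_id": ci, "member_type": "ncrna", "member_id": n})
                for d in sorted(c.diseases):
                    rows.append({"cluster_id": ci, "member_type": "disease", "member_id": d})
            frames[w] = pd.DataFrame(rows, columns=["cluster_id", "member_type", "member_id"])
        return frames

    def write(self, outdir: str | Path) -> None:
        """Write ``clusters_L{i}.tsv`` per level plus ``hierarchy.json``."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for w, frame in self.to_frames().items():
            frame.to_csv(outdir / f"clusters_L{w}.tsv", sep="\t", index=False)
        doc = {
            "alpha": self.alpha,
            "beta": self.beta,
            "levels": [
                [
                    {
                        "ncrnas": sorted(c.ncrnas),
                        "diseases": sorted(c.diseases),
                        "h": cohesiveness(c, self.rel),
                        "parents": (
                            []
                            if w == 0
                            else [
                                pi
                                for pi, p in enumerate(self.levels[w - 1])
                                if c.contains(p)
                            ]
                        ),
                    }
                    for c in level
                ]
                for w, level in enumerate(self.levels)
            ],
        }
        with open(outdir / "hierarchy.json", "w", encoding="utf-8") as fh:
            json.dump(doc, fh, indent=1, sort_keys=True)


def build_hierarchy(
    scores: ScoredPairMatrix, alpha: float = 0.2, beta: float = 0.4
) -> ClusterHierarchy:
    """Full Stage-2 construction from the scored pair matrix.

    L_1 is the biclique-merge fixpoint; each later level is one greedy merge
    pass under the cohesiveness floor alpha; the process stops at the first
    pass with no merge.
    """
    rel = filter_pairs(scores, beta)
    levels: list[list[MultiTypeCluster]] = []
    if len(rel) > 0:
        l1 = merge_bicliques(init_bicliques(rel), rel)
        if l1:
            levels.append(l1)
            while True:
                nxt = merge_level(levels[-1], rel, alpha)
                if nxt is None:
                    break
                levels.append(nxt)
    else:
        warnings.warn("empty hierarchy: no pairs passed the beta filter", stacklevel=2)
    return ClusterHierarchy(levels=levels, rel=rel, alpha=alpha, beta=beta)
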