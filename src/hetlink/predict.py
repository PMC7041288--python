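"""Stage 3 — each hierarchy level as a link predictor.

Every level L_w induces a scoring function psi on target pairs: a pair
contained in one cluster inherits that cluster's cohesiveness; a pair
contained in several (overlapping) clusters aggregates their cohesiveness
values with one of four functions — maximum, minimum, average, or the
*evidence combination* recursion

    ec(C_1) = h(C_1);   ec(C_m) = ec(C_{m-1}) + [1 - ec(C_{m-1})] * h(C_m)

over the clusters ordered by decreasing cohesiveness, which rewards pairs
suggested by several cohesive clusters.  Pairs in no cluster at a level are
omitted (evaluation treats them as score 0).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .hclus import (
    ClusterHierarchy,
    ExtractedRelationships,
    MultiTypeCluster,
    cluster_sort_key,
    cohesiveness,
)

__all__ = [
    "AGGREGATORS",
    "PredictionTable",
    "clusters_containing_pair",
    "aggregate",
    "predict_level",
]

AGGREGATORS = ("max", "min", "avg", "ec")


def clusters_containing_pair(
    level: list[MultiTypeCluster], n: str, d: str, rel: ExtractedRelationships
) -> list[MultiTypeCluster]:
    """Clusters of the level containing both endpoints, best (highest
    cohesiveness) first."""
    hits = [c for c in level if n in c.ncrnas and d in c.diseases]
    hits.sort(key=lambda c: cluster_sort_key(c, rel))
    return hits


def aggregate(hs: list[float], method: str) -> float:
    """Fuse an ordered (descending) list of cluster cohesiveness values."""
    if not hs:
        raise ValueError("aggregate requires at least one cohesiveness value")
    method = method.lower()
    if method == "max":
        return max(hs)
    if method == "min":
        return min(hs)
    if method == "avg":
        return sum(hs) / len(hs)
    if method == "ec":
        ec = hs[0]
        for h in hs[1:]:
            ec = ec + (1.0 - ec) * h
        return ec
    raise ValueError(f"unknown aggregation method {method!r}; choose from {AGGREGATORS}")


@dataclass
class PredictionTable:
    """Ranked (ncRNA, disease) predictions for one level and aggregator."""

    frame: pd.DataFrame  # columns: ncrna_id, disease_id, score, n_clusters, rank
    level: int
    method: str

    def __len__(self) -> int:
        return len(self.frame)

    def score_of(self, n: str, d: str) -> float:
        hit = self.frame[(self.frame.ncrna_id == n) & (self.frame.disease_id == d)]
        return float(hit.score.iloc[0]) if len(hit) else 0.0

    def write_tsv(self, outdir: str | Path) -> Path:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        path = outdir / f"predictions_L{self.level}_{self.method}.tsv"
        self.frame.to_csv(path, sep="\t", index=False)
        return path


def predict_level(
    hierarchy: ClusterHierarchy,
    w: int,
    method: str = "max",
    known_pairs: frozenset[tuple[str, str]] | set[tuple[str, str]] = frozenset(),
    exclude_known: bool = True,
) -> PredictionTable:
    """Score every pair co-occurring in at least one cluster of level L_w.

    With ``exclude_known`` (the default) the table lists only pairs absent
    from the training positive set — the *new* candidate links.  Rows are
    sorted by score descending, ties broken by (ncrna_id, disease_id).
    """
    level = hierarchy.level(w)
    rel = hierarchy.rel
    h_cache = {id(c): cohesiveness(c, rel) for c in level}

    membership: dict[tuple[str, str], list[MultiTypeCluster]] = {}
    for c in level:
        for n in c.ncrnas:
            for d in c.diseases:
                membership.setdefault((n, d), []).append(c)

    rows = []
    for (n, d), clusters in membership.items():
        if exclude_known and (n, d) in known_pairs:
            continue
        clusters = sorted(clusters, key=lambda c: cluster_sort_key(c, rel))
        hs = [h_cache[id(c)] for c in clusters]
        rows.append(
            {
                "ncrna_id": n,
                "disease_id": d,
                "score": aggregate(hs, method),
                "n_clusters": len(clusters),
            }
        )
    frame = pd.DataFrame(rows, columns=["ncrna_id", "disease_id", "score", "n_clusters"])
    if len(frame):
        frame = frame.sort_values(
            ["score", "ncrna_id", "disease_id"], ascending=[False, True, True]
        ).reset_index(drop=True)
    frame["rank"] = range(1, len(frame) + 1)
    return PredictionTable(frame=frame, level=w, method=method.lower())
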