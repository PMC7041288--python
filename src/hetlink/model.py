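"""Model/Results facade over the three-stage pipeline.

:class:`HeterogeneousLinkModel` holds a validated network plus the method
parameters; :meth:`~HeterogeneousLinkModel.fit` runs meta-path scoring and
hierarchy construction and returns a :class:`LinkPredictionResults`, from
which per-level ranked predictions, cross-validated ranking metrics and a
text summary are obtained.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd

from . import evaluation as ev
from .hclus import ClusterHierarchy, build_hierarchy, cohesiveness
from .hetnet import HeterogeneousNetwork, load_network
from .metapath import ScoredPairMatrix, score_all_pairs
from .predict import AGGREGATORS, PredictionTable, predict_level

__all__ = ["HeterogeneousLinkModel", "LinkPredictionResults"]


class HeterogeneousLinkModel:
    """Link prediction between the two target types of an attributed
    heterogeneous network.

    Parameters
    ----------
    network
        A validated :class:`~hetlink.hetnet.HeterogeneousNetwork`.
    alpha
        Cohesiveness floor for merging clusters above level 1 (default 0.2).
    beta
        Score threshold for a pair to count as an extracted relationship
        (default 0.4).
    depth
        Propagation depth for folding off-meta-path attributes onto
        adjacent on-path nodes (default 2).
    max_path_len
        Maximum number of edges in an enumerated meta-path (default 3).
    seq_cap
        Deterministic cap on materialized sequences per meta-path endpoint.
    """

    def __init__(
        self,
        network: HeterogeneousNetwork,
        alpha: float = 0.2,
        beta: float = 0.4,
        depth: int = 2,
        max_path_len: int = 3,
        seq_cap: int = 1000,
    ) -> None:
        if not (0.0 <= alpha <= 1.0 and 0.0 <= beta <= 1.0):
            raise ValueError("alpha and beta must be in [0, 1]")
        self.network = network
        self.alpha = alpha
        self.beta = beta
        self.depth = depth
        self.max_path_len = max_path_len
        self.seq_cap = seq_cap

    @classmethod
    def from_tables(
        cls,
        schema_file: str | Path,
        node_tables: Mapping[str, str | Path],
        edge_tables: Mapping[str, str | Path],
        **params,
    ) -> "HeterogeneousLinkModel":
        """Build the model straight from a schema file plus delimited tables."""
        return cls(load_network(schema_file, node_tables, edge_tables), **params)

    @property
    def params(self) -> dict[str, float | int]:
        return {
            "alpha": self.alpha,
            "beta": self.beta,
            "depth": self.depth,
            "max_path_len": self.max_path_len,
            "seq_cap": self.seq_cap,
        }

    def fit(self) -> "LinkPredictionResults":
        """Run scoring (stage 1) and hierarchy construction (stage 2)."""
        scores = score_all_pairs(
            self.network,
            max_len=self.max_path_len,
            depth=self.depth,
            seq_cap=self.seq_cap,
        )
        hierarchy = build_hierarchy(scores, alpha=self.alpha, beta=self.beta)
        return LinkPredictionResults(model=self, scores=scores, hierarchy=hierarchy)


@dataclass
class LinkPredictionResults:
    """Fitted scores and cluster hierarchy, with prediction/evaluation views."""

    model: HeterogeneousLinkModel
    scores: ScoredPairMatrix
    hierarchy: ClusterHierarchy
    _known: frozenset = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._known = frozenset(self.model.network.known_target_pairs())

    # -- prediction ----------------------------------------------------

    def predict(
        self, level: int = 1, method: str = "max", exclude_known: bool = True
    ) -> PredictionTable:
        """Ranked candidate links from hierarchy level ``level``."""
        return predict_level(
            self.hierarchy,
            level,
            method=method,
            known_pairs=self._known,
            exclude_known=exclude_known,
        )

    def predict_all(self, exclude_known: bool = True) -> dict[tuple[int, str], PredictionTable]:
        return {
            (w, m): self.predict(w, m, exclude_known)
            for w in range(1, self.hierarchy.depth + 1)
            for m in AGGREGATORS
        }

    # -- evaluation ----------------------------------------------------

    def evaluate(
        self,
        n_folds: int = 10,
        seed: int = 0,
        method: str = "max",
        k_max: int = 5000,
    ) -> pd.DataFrame:
        """Edge-holdout cross-validation of the full pipeline.

        Each fold refits the model on the network minus the held-out direct
        target links and scores the resulting ranking against them.
        Returns one row per (fold, level) with AUTPR@k, AUROC and AUPR.
        """
        net = self.model.network
        ncrnas, diseases = net.target_nodes()
        candidates = [(n, d) for n in ncrnas for d in diseases]
        rows = []
        for fold in ev.make_folds(net, n_folds=n_folds, seed=seed):
            sub = HeterogeneousLinkModel(fold.train_network, **self.model.params)
            res = sub.fit()
            train_known = frozenset(fold.train_network.known_target_pairs())
            cands = [p for p in candidates if p not in train_known]
            for w in range(1, max(res.hierarchy.depth, 1) + 1):
                if w > res.hierarchy.depth:
                    continue
                table = res.predict(w, method)
                metrics = ev.roc_pr_unknown_neg(
                    table, fold.test_pairs, cands, k_max=k_max
                )
                rows.append(
                    {"fold": fold.index, "level": w, "method": method, **metrics.to_row()}
                )
        return pd.DataFrame(rows)

    # -- reporting -----------------------------------------------------

    def summary(self) -> str:
        """Text table of the fitted hierarchy and scoring diagnostics."""
        net = self.model.network
        ncrnas, diseases = net.target_nodes()
        lines = [
            "Heterogeneous link prediction results",
            "=" * 53,
            f"target types        : {net.schema.target_types[0]} x {net.schema.target_types[1]}",
            f"target nodes        : {len(ncrnas)} x {len(diseases)}",
            f"known direct links  : {len(self._known)}",
            f"scored pairs (s>0)  : {len(self.scores.scores)}",
            f"retained (s >= beta): {len(self.hierarchy.rel)}",
            f"parameters          : alpha={self.model.alpha} beta={self.model.beta} "
            f"depth={self.model.depth} max_path_len={self.model.max_path_len}",
            "-" * 53,
            f"{'level':>5} {'clusters':>9} {'mean h':>8} {'max size':>9}",
        ]
        for w, level in enumerate(self.hierarchy.levels, start=1):
            hs = [cohesiveness(c, self.hierarchy.rel) for c in level]
            sizes = [len(c.ncrnas) + len(c.diseases) for c in level]
            lines.append(
                f"{w:>5} {len(level):>9} {sum(hs) / len(hs):>8.3f} {max(sizes):>9}"
            )
        if not self.hierarchy.levels:
            lines.append("  (empty hierarchy)")
        lines.append("=" * 53)
        return "\n".join(lines)
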