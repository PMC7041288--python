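"""Ranking-based evaluation: edge-holdout cross-validation, TPR@k,
AUTPR@k, and ROC/PR curves under the unknowns-as-negatives assumption.

The datasets carry only validated (positive) links, so precision-style
measures need an assumption about unknown pairs.  Two protocols are
provided:

* **TPR@k** — the fraction of held-out validated pairs ranked in the top k
  of the prediction list, plotted over k, with the area under that curve
  (AUTPR@k) as a scalar summary.  AUTPR@k is the area of the
  right-continuous TPR@k step curve over k in [1, k_max], normalised by
  (k_max - 1) so a ranking that places every positive at the very top
  scores 1.
* **ROC / PR** — standard curves with every non-validated pair treated as
  negative.  Because that assumption is wrong for genuinely novel links,
  these numbers support only relative comparison between rankings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import auc, precision_recall_curve, roc_curve

from .hetnet import HeterogeneousNetwork
from .predict import PredictionTable

__all__ = [
    "FoldSplit",
    "RankingMetrics",
    "make_folds",
    "complete_ranking",
    "tpr_at_k",
    "tpr_curve",
    "autpr_at_k",
    "roc_pr_unknown_neg",
    "plot_tpr_curve",
]


@dataclass
class FoldSplit:
    """One cross-validation fold: held-out positives + training network."""

    index: int
    test_pairs: set[tuple[str, str]]
    train_network: HeterogeneousNetwork


def make_folds(
    net: HeterogeneousNetwork, n_folds: int = 10, seed: int = 0
) -> list[FoldSplit]:
    """Seeded partition of the known positive pairs into ``n_folds`` folds.

    Each training network is the original minus that fold's direct
    target-target edges; all nodes are retained (transductive protocol).
    """
    positives = sorted(net.known_target_pairs())
    if len(positives) < n_folds:
        raise ValueError(
            f"{len(positives)} positive pairs cannot fill {n_folds} folds"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(positives))
    folds = []
    for i, chunk in enumerate(np.array_split(order, n_folds)):
        held = {positives[j] for j in chunk}
        train = net.copy()
        train.remove_target_edges(held)
        folds.append(FoldSplit(index=i, test_pairs=held, train_network=train))
    return folds


def complete_ranking(
    table: PredictionTable | pd.DataFrame,
    candidates: list[tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """Ranked frame extended with unranked candidate pairs at score 0.

    Unranked pairs are appended in lexicographic order so TPR@k is defined
    for every k up to the full candidate count.
    """
    frame = table.frame if isinstance(table, PredictionTable) else table
    frame = frame[["ncrna_id", "disease_id", "score"]].copy()
    if candidates is not None:
        ranked = set(zip(frame.ncrna_id, frame.disease_id))
        missing = sorted(p for p in candidates if p not in ranked)
        if missing:
            extra = pd.DataFrame(missing, columns=["ncrna_id", "disease_id"])
            extra["score"] = 0.0
            frame = pd.concat([frame, extra], ignore_index=True)
    frame["rank"] = range(1, len(frame) + 1)
    return frame


def _positive_ranks(ranked: pd.DataFrame, positives: set[tuple[str, str]]) -> np.ndarray:
    mask = [
        (n, d) in positives for n, d in zip(ranked.ncrna_id, ranked.disease_id)
    ]
    return ranked.loc[mask, "rank"].to_numpy()


def tpr_at_k(
    ranked: PredictionTable | pd.DataFrame, positives: set[tuple[str, str]], k: int
) -> float:
    """Fraction of the validated pairs found in the top k: TP / (TP + FN)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if not positives:
        raise ValueError("positive set is empty")
    frame = complete_ranking(ranked)
    ranks = _positive_ranks(frame, positives)
    return float(np.sum(ranks <= k)) / len(positives)


def tpr_curve(
    ranked: PredictionTable | pd.DataFrame,
    positives: set[tuple[str, str]],
    k_max: int,
) -> pd.DataFrame:
    """TPR@k for k = 1..k_max as a two-column frame (k, tpr)."""
    if not positives:
        raise ValueError("positive set is empty")
    frame = complete_ranking(ranked)
    ranks = _positive_ranks(frame, positives)
    ks = np.arange(1, k_max + 1)
    hits = np.zeros(k_max + 1)
    in_range = ranks[ranks <= k_max].astype(int)
    np.add.at(hits, in_range, 1.0)
    tpr = np.cumsum(hits)[1:] / len(positives)
    return pd.DataFrame({"k": ks, "tpr": tpr})


def autpr_at_k(
    ranked: PredictionTable | pd.DataFrame,
    positives: set[tuple[str, str]],
    k_max: int = 5000,
) -> float:
    """Normalised area under the TPR@k step curve over k in [1, k_max].

    Computed as sum_{k=2..k_max} TPR@k / (k_max - 1): the exact integral of
    the right-continuous step curve, scaled so a ranking with every
    positive at the top scores 1.
    """
    if k_max < 1:
        raise ValueError("k_max must be >= 1")
    if k_max == 1:
        return tpr_at_k(ranked, positives, 1)
    curve = tpr_curve(ranked, positives, k_max)
    return float(curve.tpr.to_numpy()[1:].sum()) / (k_max - 1)


@dataclass
class RankingMetrics:
    """Curve coordinates and scalar areas for one ranking.

    ROC/PR values rest on the unknowns-as-negatives assumption and are
    labelled for relative comparison only.
    """

    tpr_at_k: pd.DataFrame
    autpr: float
    roc_points: pd.DataFrame
    pr_points: pd.DataFrame
    auroc: float
    aupr: float
    note: str = field(default="relative comparison only", repr=False)

    def to_row(self) -> dict[str, float]:
        return {"autpr": self.autpr, "auroc": self.auroc, "aupr": self.aupr}


def roc_pr_unknown_neg(
    ranked: PredictionTable | pd.DataFrame,
    positives: set[tuple[str, str]],
    candidates: list[tuple[str, str]],
    k_max: int = 5000,
) -> RankingMetrics:
    """ROC and PR curves treating every non-validated candidate as negative."""
    frame = complete_ranking(ranked, candidates)
    y_true = np.array(
        [(n, d) in positives for n, d in zip(frame.ncrna_id, frame.disease_id)],
        dtype=int,
    )
    y_score = frame.score.to_numpy()
    if y_true.all() or not y_true.any():
        raise ValueError("ROC/PR need both positive and negative candidates")
    fpr, tpr, _ = roc_curve(y_true, y_score)
    precision, recall, _ = precision_recall_curve(y_true, y_score)
    curve = tpr_curve(frame, positives, min(k_max, len(frame)))
    return RankingMetrics(
        tpr_at_k=curve,
        autpr=autpr_at_k(frame, positives, k_max=min(k_max, len(frame))),
        roc_points=pd.DataFrame({"fpr": fpr, "tpr": tpr}),
        pr_points=pd.DataFrame({"recall": recall, "precision": precision}),
        auroc=float(auc(fpr, tpr)),
        aupr=float(auc(recall, precision)),
    )


def plot_tpr_curve(metrics: RankingMetrics, path: str) -> None:
    """Save the TPR@k curve as a figure (optional diagnostic output)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.step(metrics.tpr_at_k.k, metrics.tpr_at_k.tpr, where="post")
    ax.set_xlabel("k")
    ax.set_ylabel("TPR@k")
    ax.set_ylim(0, 1.02)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
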