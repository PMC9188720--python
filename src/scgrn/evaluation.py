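"""ROC/AUC evaluation of ranked edge lists and the method-ranking table.

The ROC curve sweeps a threshold over the pooled edge scores from high to
low; TPR is the fraction of gold edges recovered, FPR the fraction of
non-edges falsely called.  AUC is computed as the Mann-Whitney probability
that a random true edge outscores a random non-edge (ties counted 1/2),
which equals the trapezoidal area under the ROC curve.

``rank_methods`` builds the methods x (dataset, CV-scheme) rank table:
rank 1 is the best AUC in each combination, ties receive their average
rank, and each method is summarised by its mean rank across combinations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import sklearn.metrics
from scipy.stats import rankdata

__all__ = ["ROCCurve", "RankTable", "roc_curve", "auc", "per_tf_auc", "rank_methods"]


@dataclass(frozen=True)
class ROCCurve:
    fpr: np.ndarray  # nondecreasing, 0 -> 1
    tpr: np.ndarray  # nondecreasing, 0 -> 1
    thresholds: np.ndarray  # decreasing score cutoffs (first entry = +inf)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"fpr": self.fpr, "tpr": self.tpr, "threshold": self.thresholds}
        )


def _check_scores_labels(scores, labels):
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be 1-D and equal length")
    if not np.isfinite(scores).all():
        raise ValueError("scores must be finite")
    if not set(np.unique(labels)) <= {-1, 1}:
        raise ValueError("labels must be ±1")
    if (labels == 1).sum() == 0 or (labels == -1).sum() == 0:
        raise ValueError("need at least one positive and one negative label")
    return scores, labels


def roc_curve(scores, labels) -> ROCCurve:
    """Threshold sweep over distinct scores, descending; tied scores
    collapse into a single curve vertex."""
    scores, labels = _check_scores_labels(scores, labels)
    fpr, tpr, thr = sklearn.metrics.roc_curve(
        labels, scores, pos_label=1, drop_intermediate=False
    )
    return ROCCurve(fpr, tpr, thr)


def auc(scores, labels) -> float:
    """Area under the ROC curve via the rank-sum (Mann-Whitney) identity.

    Equals sum over (positive, negative) pairs of [score_pos > score_neg]
    with ties counted 1/2, divided by n_pos * n_neg; identical to the
    trapezoidal area under :func:`roc_curve`.
    """
    scores, labels = _check_scores_labels(scores, labels)
    pos = labels == 1
    n_pos = int(pos.sum())
    n_neg = int(len(labels) - n_pos)
    ranks = rankdata(scores)  # average ranks handle ties at exactly 1/2
    rank_sum = ranks[pos].sum()
    return float((rank_sum - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def per_tf_auc(table: pd.DataFrame) -> pd.Series:
    """AUC per TF over its own held-out scores; TFs whose candidates are
    single-class (e.g. zero-positive TFs) are omitted."""
    out = {}
    for tf, group in table.groupby("tf", sort=True):
        labels = group["label"].to_numpy()
        if (labels == 1).any() and (labels == -1).any():
            out[tf] = auc(group["score"].to_numpy(), labels)
    return pd.Series(out, name="auc")


def pooled_auc(table: pd.DataFrame) -> float:
    """AUC of the pooled edge table (all TFs' held-out scores together)."""
    return auc(table["score"].to_numpy(), table["label"].to_numpy())


@dataclass(frozen=True)
class RankTable:
    """Methods x (dataset, scheme) ranks with an average-rank summary."""

    methods: tuple[str, ...]
    combos: tuple[tuple[str, str], ...]
    ranks: np.ndarray  # (n_methods, n_combos); ties carry average ranks
    avg_rank: np.ndarray  # mean over combos, full precision

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(
            self.ranks,
            index=list(self.methods),
            columns=[f"{d}/{s}" for d, s in self.combos],
        )
        frame["avg_rank"] = self.avg_rank
        return frame


def rank_methods(auc_by_method_and_combo: dict) -> RankTable:
    """Rank methods by AUC within each (dataset, scheme) combination.

    ``auc_by_method_and_combo`` maps (method, (dataset, scheme)) -> AUC and
    must be complete over the cartesian product of its methods and combos.
    Rank 1 = highest AUC; tied AUCs share their average rank.
    """
    methods = tuple(sorted({m for m, _ in auc_by_method_and_combo}))
    combos = tuple(sorted({c for _, c in auc_by_method_and_combo}))
    if not methods or not combos:
        raise ValueError("empty AUC map")
    values = np.empty((len(methods), len(combos)))
    for i, m in enumerate(methods):
        for j, c in enumerate(combos):
            if (m, c) not in auc_by_method_and_combo:
                raise ValueError(f"missing AUC for method {m!r}, combo {c!r}")
            values[i, j] = auc_by_method_and_combo[(m, c)]
    ranks = np.empty_like(values)
    for j in range(len(combos)):
        ranks[:, j] = rankdata(-values[:, j])  # 1 = best, ties averaged
    return RankTable(methods, combos, ranks, ranks.mean(axis=1))
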