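"""Per-TF classification problems and cross-validation splits.

For a transcription factor *t*, every other gene in the gold network's
universe is a candidate target; the candidate's feature vector is its raw
expression profile across all cells, and its label is +1 iff (t, candidate)
is a gold-standard edge.  The TF identity lives in the problem object, not
in the features.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import KFold, StratifiedKFold

from scgrn.data_io import ExpressionMatrix, GoldNetwork

__all__ = ["TFProblem", "CVScheme", "build_tf_problem", "make_cv_splits"]


@dataclass(frozen=True)
class TFProblem:
    """One TF's supervised dataset: candidate genes x cells, with ±1 labels."""

    tf_id: str
    sample_ids: tuple[str, ...]
    features: np.ndarray  # (n_candidates, n_cells)
    labels: np.ndarray  # ±1, aligned with sample_ids

    @property
    def n_positives(self) -> int:
        return int((self.labels == 1).sum())


@dataclass(frozen=True)
class CVScheme:
    """Cross-validation scheme: leave-one-out or (stratified) k-fold.

    k-fold is stratified by default so no fold is positive-free by chance;
    ``seed`` fixes the shuffle and is mandatory for reproducibility.
    """

    kind: str  # "loocv" | "kfold"
    k: int = 5
    seed: int = 0
    stratified: bool = True

    def __post_init__(self) -> None:
        if self.kind not in ("loocv", "kfold"):
            raise ValueError(f"unknown CV kind {self.kind!r}")
        if self.kind == "kfold" and self.k < 2:
            raise ValueError(f"kfold requires k >= 2, got {self.k}")

    @property
    def name(self) -> str:
        return "loocv" if self.kind == "loocv" else f"{self.k}fold"


def build_tf_problem(
    expr: ExpressionMatrix, net: GoldNetwork, tf: str
) -> TFProblem:
    """Assemble the labeled dataset for one TF.

    Candidates are all universe genes except the TF itself (the TF is kept
    as its own candidate only when a gold self-edge exists), ordered as in
    the expression matrix.  Feature rows are copied unmodified.
    """
    gene_set = set(expr.gene_ids)
    if tf not in gene_set:
        raise ValueError(f"TF {tf!r} absent from expression matrix")
    missing = net.gene_universe - gene_set
    if missing:
        raise ValueError(
            f"gold network genes missing from expression matrix: "
            f"{sorted(missing)[:5]}"
        )
    positives = net.targets_of(tf)
    keep_self = (tf, tf) in net.edges
    sample_ids = tuple(
        g
        for g in expr.gene_ids
        if g in net.gene_universe and (g != tf or keep_self)
    )
    if not sample_ids:
        raise ValueError(f"TF {tf!r} has an empty candidate set")
    rows = [expr.gene_index(g) for g in sample_ids]
    features = expr.values[rows].copy()
    labels = np.array([1 if g in positives else -1 for g in sample_ids], dtype=int)
    return TFProblem(tf, sample_ids, features, labels)


def make_cv_splits(
    n_samples: int, labels: np.ndarray, scheme: CVScheme
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Deterministic train/test index splits for one TF problem.

    LOOCV yields ``n_samples`` splits with singleton test sets in index
    order.  k-fold yields k splits whose test sets partition the indices
    and differ in size by at most one; stratified k-fold additionally
    preserves class proportions per fold up to rounding.  Identical
    (labels, scheme) inputs give identical splits.
    """
    labels = np.asarray(labels)
    if n_samples < 2:
        raise ValueError("need at least 2 samples to cross-validate")
    if labels.shape[0] != n_samples:
        raise ValueError("labels length must equal n_samples")

    if scheme.kind == "loocv":
        indices = np.arange(n_samples)
        return [
            (np.delete(indices, i), np.array([i]))
            for i in range(n_samples)
        ]

    if scheme.k > n_samples:
        raise ValueError(
            f"kfold with k={scheme.k} impossible for {n_samples} samples"
        )
    class_counts = np.unique(labels, return_counts=True)[1]
    # stratification is only possible when some class has >= k members
    if scheme.stratified and len(class_counts) > 1 and class_counts.max() >= scheme.k:
        splitter = StratifiedKFold(
            n_splits=scheme.k, shuffle=True, random_state=scheme.seed
        )
        with warnings.catch_warnings():
            # folds with fewer members of a class than k are expected for
            # low-degree TFs; the engine's zero-positive fold rule covers them
            warnings.simplefilter("ignore", UserWarning)
            splits = list(splitter.split(np.zeros((n_samples, 1)), labels))
    else:
        splitter = KFold(n_splits=scheme.k, shuffle=True, random_state=scheme.seed)
        splits = list(splitter.split(np.zeros((n_samples, 1))))
    return [(np.sort(tr), np.sort(te)) for tr, te in splits]
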