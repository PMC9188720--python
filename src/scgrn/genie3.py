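"""GENIE3-style unsupervised baseline.

For every target gene a random-forest regression predicts its expression
across cells from the expression of the candidate regulators (excluding the
target itself); the importance of regulator r for target g — the total
variance reduction attributed to r over the ensemble — is the score of edge
(r, g).  Importances are normalised to sum to one per target so scores are
comparable when pooled across targets.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

from scgrn.data_io import ExpressionMatrix, GoldNetwork
from scgrn.engine import EDGE_COLUMNS

__all__ = ["genie3_scores", "importance_to_edge_table"]


def genie3_scores(
    expr: ExpressionMatrix,
    regulators,
    targets,
    n_trees: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Importance matrix: rows = candidate regulators, columns = targets.

    Each column holds nonnegative importances summing to 1 (or all zero for
    a constant target).  Self-regulation entries are always 0.  Cells are
    put in a canonical order (sorted by id) before fitting, so scores do
    not depend on the column order of the input matrix.
    """
    regulators = sorted(map(str, regulators))
    targets = sorted(map(str, targets))
    gene_set = set(expr.gene_ids)
    for g in (*regulators, *targets):
        if g not in gene_set:
            raise ValueError(f"gene {g!r} not in expression matrix")
    if n_trees < 1:
        raise ValueError("n_trees must be >= 1")

    cell_order = np.argsort(np.asarray(expr.cell_ids))
    profiles = {
        g: expr.values[expr.gene_index(g)][cell_order] for g in set(regulators) | set(targets)
    }
    imp = pd.DataFrame(0.0, index=regulators, columns=targets)
    rng = np.random.default_rng(seed)
    for g in targets:
        y = profiles[g]
        if np.ptp(y) == 0.0:  # constant target: no variance to explain
            continue
        preds = [r for r in regulators if r != g]
        if not preds:
            continue
        X = np.column_stack([profiles[r] for r in preds])
        forest = RandomForestRegressor(
            n_estimators=n_trees,
            max_features="sqrt",
            random_state=int(rng.integers(2**31 - 1)),
        )
        forest.fit(X, y)
        importances = forest.feature_importances_
        total = importances.sum()
        if total > 0:
            importances = importances / total
        imp.loc[preds, g] = importances
    return imp


def importance_to_edge_table(imp: pd.DataFrame, net: GoldNetwork) -> pd.DataFrame:
    """Restrict an importance matrix to the (tf, candidate) pairs the
    supervised pipeline scores, labelled from the gold network.

    Candidates of a TF are all universe genes except the TF itself (plus
    the TF when a gold self-edge exists), matching the supervised runs;
    ``fold`` is -1 throughout (no cross-validation is involved).
    """
    tfs = sorted(net.tf_set)
    missing_tfs = [tf for tf in tfs if tf not in imp.index]
    if missing_tfs:
        raise ValueError(f"TFs missing from importance matrix: {missing_tfs[:5]}")
    records = []
    for tf in tfs:
        positives = net.targets_of(tf)
        keep_self = (tf, tf) in net.edges
        for g in sorted(net.gene_universe):
            if g == tf and not keep_self:
                continue
            if g not in imp.columns:
                raise ValueError(f"candidate {g!r} missing from importance matrix")
            score = float(imp.at[tf, g])
            records.append((tf, g, score, 1 if g in positives else -1, -1))
    return pd.DataFrame(records, columns=EDGE_COLUMNS)
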