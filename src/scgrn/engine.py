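"""Orchestration: loop over TFs, cross-validate, pool held-out edge scores.

For each TF the engine builds the candidate-target problem, applies the
zero-positive rule (a TF with no known targets gets score 0.0 for every
candidate — no training), and otherwise trains on each CV training fold and
scores its held-out test fold.  A training fold that itself contains no
positive (possible under LOOCV when a TF's only positive is held out)
likewise scores its test samples 0.0.  The pooled records over all TFs are
the inferred network: one (tf, target, score, label, fold) row per pair,
every score produced by a model that never saw that pair's label.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from scgrn.classifiers import ClassifierConfig, score_samples, train_classifier
from scgrn.data_io import ExpressionMatrix, GoldNetwork
from scgrn.problems import CVScheme, build_tf_problem, make_cv_splits

logger = logging.getLogger(__name__)

__all__ = ["infer_grn", "run_benchmark"]

EDGE_COLUMNS = ["tf", "target", "score", "label", "fold"]


def _records_for_tf(
    problem, config: ClassifierConfig, scheme: CVScheme
) -> list[tuple]:
    tf = problem.tf_id
    n = len(problem.sample_ids)
    if problem.n_positives == 0:
        # zero-positive rule: no training signal, classify every candidate negative
        logger.info("TF %s: 0 positives of %d candidates, zero-positive rule", tf, n)
        return [
            (tf, g, 0.0, int(lab), -1)
            for g, lab in zip(problem.sample_ids, problem.labels)
        ]

    logger.info("TF %s: %d positives of %d candidates", tf, problem.n_positives, n)
    records: list[tuple] = []
    splits = make_cv_splits(n, problem.labels, scheme)
    for fold_id, (train_idx, test_idx) in enumerate(splits):
        train_labels = problem.labels[train_idx]
        classes = np.unique(train_labels)
        if len(classes) < 2:
            # fold-level extension of the zero-positive rule
            fill = 0.0 if classes[0] == -1 else 1.0
            scores = np.full(len(test_idx), fill)
        else:
            model = train_classifier(
                config, problem.features[train_idx], train_labels
            )
            scores = score_samples(model, problem.features[test_idx])
        for i, s in zip(test_idx, scores):
            records.append(
                (tf, problem.sample_ids[i], float(s), int(problem.labels[i]), fold_id)
            )
    return records


def infer_grn(
    expr: ExpressionMatrix,
    net: GoldNetwork,
    config: ClassifierConfig,
    scheme: CVScheme,
    tfs=None,
) -> pd.DataFrame:
    """Infer the full GRN: pooled held-out edge scores over every TF.

    ``tfs`` defaults to the network's TF set (sources of gold edges) but
    may name additional regulators with no known targets; those fall under
    the zero-positive rule.  Returns a DataFrame with columns tf, target,
    score, label, fold — exactly one row per (TF, candidate target) pair.
    ``fold`` is -1 for rows produced by the zero-positive rule.
    """
    tfs = sorted(net.tf_set) if tfs is None else sorted(map(str, tfs))
    if not tfs:
        raise ValueError("gold network has no TFs")
    records: list[tuple] = []
    for tf in tfs:
        try:
            problem = build_tf_problem(expr, net, tf)
            records.extend(_records_for_tf(problem, config, scheme))
        except Exception as exc:
            raise RuntimeError(f"GRN inference failed for TF {tf!r}: {exc}") from exc
    return pd.DataFrame(records, columns=EDGE_COLUMNS)


def run_benchmark(
    expr: ExpressionMatrix,
    net: GoldNetwork,
    configs: list[ClassifierConfig],
    schemes: list[CVScheme],
) -> dict[tuple[str, str], pd.DataFrame]:
    """One :func:`infer_grn` table per (method, scheme) pair.

    All methods share a scheme's splits (splits depend only on labels and
    the scheme's seed), so classifiers are compared on identical folds.
    """
    if not configs or not schemes:
        raise ValueError("configs and schemes must be nonempty")
    results: dict[tuple[str, str], pd.DataFrame] = {}
    for scheme in schemes:
        for config in configs:
            key = (config.method, scheme.name)
            logger.info("benchmark: method=%s scheme=%s", *key)
            try:
                results[key] = infer_grn(expr, net, config, scheme)
            except Exception as exc:
                raise RuntimeError(
                    f"benchmark failed at method={config.method}, "
                    f"scheme={scheme.name}: {exc}"
                ) from exc
    return results
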