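"""Full benchmark workflow: many methods x many CV schemes on one dataset,
with ranked outputs and a reproducibility manifest."""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path

import sklearn

import scgrn
from scgrn.classifiers import METHODS, ClassifierConfig
from scgrn.data_io import (
    ExpressionMatrix,
    GoldNetwork,
    read_expression,
    read_network,
    write_edge_scores,
)
from scgrn.engine import run_benchmark
from scgrn.evaluation import pooled_auc, rank_methods, roc_curve
from scgrn.genie3 import genie3_scores, importance_to_edge_table
from scgrn.problems import CVScheme

__all__ = ["RunConfig", "run_full_benchmark"]


@dataclass(frozen=True)
class RunConfig:
    """Declarative description of one benchmark run."""

    expr_path: str
    network_path: str
    outdir: str
    methods: tuple[str, ...] = METHODS
    schemes: tuple[tuple[str, int], ...] = (
        ("loocv", 0),
        ("kfold", 3),
        ("kfold", 5),
        ("kfold", 10),
    )
    seed: int = 0
    include_genie3: bool = True
    genie3_trees: int = 100
    dataset_name: str = "dataset"
    classifier_overrides: dict = field(default_factory=dict)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _schemes(cfg: RunConfig) -> list[CVScheme]:
    out = []
    for kind, k in cfg.schemes:
        if kind == "loocv":
            out.append(CVScheme("loocv", seed=cfg.seed))
        else:
            out.append(CVScheme("kfold", k=k, seed=cfg.seed))
    return out


def run_full_benchmark(cfg: RunConfig) -> dict:
    """Run every (method, scheme) combination and write the artifact set.

    Writes, under ``cfg.outdir``: one edge-score TSV and one ROC TSV plus
    an AUC entry per combination, a rank table TSV over the configured
    methods, GENIE3 baseline outputs (reported alongside but excluded from
    the method ranking), and a JSON run manifest.  Returns the manifest.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    expr = read_expression(cfg.expr_path)
    net = read_network(cfg.network_path, expr.gene_ids)

    configs = [
        ClassifierConfig(method=m, seed=cfg.seed, **cfg.classifier_overrides.get(m, {}))
        for m in cfg.methods
    ]
    schemes = _schemes(cfg)
    tables = run_benchmark(expr, net, configs, schemes)

    aucs: dict[tuple[str, tuple[str, str]], float] = {}
    for (method, scheme_name), table in tables.items():
        stem = outdir / f"{method}.{scheme_name}"
        write_edge_scores(table, f"{stem}.edges.tsv")
        value = pooled_auc(table)
        aucs[(method, (cfg.dataset_name, scheme_name))] = value
        curve = roc_curve(table["score"].to_numpy(), table["label"].to_numpy())
        curve.to_frame().to_csv(f"{stem}.roc.tsv", sep="\t", index=False)

    rank_table = rank_methods(aucs)
    rank_table.to_frame().to_csv(outdir / "rank_table.tsv", sep="\t")

    genie3_auc = None
    if cfg.include_genie3:
        imp = genie3_scores(
            expr, net.tf_set, net.gene_universe, n_trees=cfg.genie3_trees, seed=cfg.seed
        )
        table = importance_to_edge_table(imp, net)
        write_edge_scores(table, outdir / "genie3.edges.tsv")
        genie3_auc = pooled_auc(table)

    manifest = {
        "config": asdict(cfg),
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "auc": {f"{m}/{c[1]}": v for (m, c), v in aucs.items()},
        "genie3_auc": genie3_auc,
        "versions": {
            "python": platform.python_version(),
            "scgrn": scgrn.__version__,
            "scikit-learn": sklearn.__version__,
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
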