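"""Synthetic single-cell expression with a planted regulatory network.

The generator emulates the shape of small published single-cell benchmarks:
tens of genes of which a subset are TFs, a few hundred cells, a sparse
directed TF -> target network, and zero-inflated non-negative expression.

Generative model (per cell, all on the natural-log scale):

* each TF's log-expression is i.i.d. Gaussian, so TF profiles are
  log-normal across cells;
* each (TF, target) edge is present independently with probability
  ``edge_density``; each TF acts consistently as an activator or repressor
  (sign drawn once per TF, equiprobable);
* a regulated target's log-expression is a baseline plus the sum of its
  regulators' responses — Hill ``x^h / (K^h + x^h)`` with h=2 and K the
  regulator's median level (or a linear ramp), centred so the response is 0
  at the median regulator level — scaled by ``effect_strength``;
* additive Gaussian noise (``noise_sd``) on the log scale;
* finally each matrix entry is independently zeroed with probability
  ``dropout_rate`` (uniform technical dropout).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from scgrn.data_io import ExpressionMatrix, GoldNetwork

__all__ = ["SimulationConfig", "simulate", "shuffle_labels"]

_LOG_MEAN = 1.0  # baseline log-expression
_LOG_SD = 0.5  # between-cell spread of TF / unregulated-gene log levels
_HILL_H = 2.0


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the planted-network generator.

    Defaults give 10 TFs, 90 targets, 400 cells, ~13-14 targets per TF
    (density 0.15), a Hill response of strength 2, log-scale noise 0.3 and
    30% dropout — comparable in size and sparsity to the small real
    single-cell benchmarks this pipeline is aimed at.
    """

    n_tfs: int = 10
    n_targets: int = 90
    n_cells: int = 400
    edge_density: float = 0.15
    effect: str = "hill"
    effect_strength: float = 2.0
    noise_sd: float = 0.3
    dropout_rate: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_tfs, self.n_targets, self.n_cells) < 1:
            raise ValueError("n_tfs, n_targets and n_cells must all be >= 1")
        if not 0.0 <= self.edge_density <= 1.0:
            raise ValueError("edge_density must be in [0, 1]")
        if self.effect not in ("hill", "linear"):
            raise ValueError(f"unknown effect family {self.effect!r}")
        if self.effect_strength <= 0:
            raise ValueError("effect_strength must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")

    def with_seed(self, seed: int) -> "SimulationConfig":
        return replace(self, seed=seed)


def _response(x: np.ndarray, effect: str) -> np.ndarray:
    """Regulator response in [0, 1]-ish units, equal to 1/2 at the
    regulator's median level."""
    K = np.median(x)
    if K <= 0:
        K = 1.0
    if effect == "hill":
        return x**_HILL_H / (K**_HILL_H + x**_HILL_H)
    return np.clip(x / (2.0 * K), 0.0, 1.5)


def simulate(config: SimulationConfig) -> tuple[ExpressionMatrix, GoldNetwork]:
    """Draw one expression matrix and its planted gold network."""
    rng = np.random.default_rng(config.seed)
    tf_ids = tuple(f"TF{i + 1:02d}" for i in range(config.n_tfs))
    target_ids = tuple(f"G{i + 1:03d}" for i in range(config.n_targets))
    cell_ids = tuple(f"C{i + 1:04d}" for i in range(config.n_cells))
    gene_ids = tf_ids + target_ids

    tf_log = rng.normal(_LOG_MEAN, _LOG_SD, size=(config.n_tfs, config.n_cells))
    tf_expr = np.exp(tf_log)

    adjacency = rng.random((config.n_tfs, config.n_targets)) < config.edge_density
    tf_sign = rng.choice([-1.0, 1.0], size=config.n_tfs)

    responses = np.stack(
        [_response(tf_expr[i], config.effect) for i in range(config.n_tfs)]
    )  # (n_tfs, n_cells), centred below

    target_log = np.empty((config.n_targets, config.n_cells))
    for j in range(config.n_targets):
        regs = np.flatnonzero(adjacency[:, j])
        if regs.size:
            signal = sum(
                tf_sign[i] * (responses[i] - 0.5) for i in regs
            )
            target_log[j] = _LOG_MEAN + config.effect_strength * signal
        else:
            target_log[j] = rng.normal(_LOG_MEAN, _LOG_SD, size=config.n_cells)
    target_log += rng.normal(0.0, config.noise_sd, size=target_log.shape)

    values = np.vstack([tf_expr, np.exp(target_log)])
    if config.dropout_rate > 0:
        keep = rng.random(values.shape) >= config.dropout_rate
        values = values * keep

    edges = frozenset(
        (tf_ids[i], target_ids[j]) for i, j in zip(*np.nonzero(adjacency))
    )
    net = GoldNetwork(edges, frozenset(gene_ids))
    return ExpressionMatrix(gene_ids, cell_ids, values), net


def shuffle_labels(net: GoldNetwork, seed: int) -> GoldNetwork:
    """Degree-preserving null network: each TF keeps its out-degree but its
    targets are redrawn uniformly without replacement."""
    rng = np.random.default_rng(seed)
    universe = sorted(net.gene_universe)
    edges: set[tuple[str, str]] = set()
    for tf in sorted(net.tf_set):
        degree = net.out_degree(tf)
        pool = [g for g in universe if g != tf]
        chosen = rng.choice(len(pool), size=degree, replace=False)
        edges.update((tf, pool[i]) for i in chosen)
    return GoldNetwork(frozenset(edges), net.gene_universe)
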