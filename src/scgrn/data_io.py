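"""Readers and writers for expression matrices, gold-standard networks and
ranked edge lists.

Expression matrices are delimited text (TSV/CSV, sniffed by extension) with a
header row of cell ids and a first column of gene ids, or MatrixMarket
``.mtx`` triplets with ``<prefix>.genes.txt`` / ``<prefix>.cells.txt``
sidecar files (one id per line).  Gold networks are two-column TF -> target
edge lists.  All id matching is exact and case-sensitive.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "GoldNetwork",
    "read_expression",
    "read_network",
    "write_edge_scores",
    "read_edge_scores",
]


@dataclass(frozen=True)
class ExpressionMatrix:
    """Genes x cells non-negative expression values with stable identifiers.

    Rows are genes, columns are cells (cells are the observations).  Values
    are taken as given — no normalisation or log transform is applied.
    """

    gene_ids: tuple[str, ...]
    cell_ids: tuple[str, ...]
    values: np.ndarray  # shape (n_genes, n_cells), float, finite, >= 0

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "gene_ids", tuple(str(g) for g in self.gene_ids))
        object.__setattr__(self, "cell_ids", tuple(str(c) for c in self.cell_ids))
        object.__setattr__(self, "values", values)
        if values.ndim != 2:
            raise ValueError(f"expression values must be 2-D, got shape {values.shape}")
        if values.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValueError(
                f"shape {values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.cell_ids)} cells"
            )
        if values.size == 0:
            raise ValueError("empty expression matrix")
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.cell_ids, "cell")
        bad = ~np.isfinite(values)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"non-finite expression value at gene {self.gene_ids[i]!r}, "
                f"cell {self.cell_ids[j]!r}"
            )
        neg = values < 0
        if neg.any():
            i, j = np.argwhere(neg)[0]
            raise ValueError(
                f"negative expression value {values[i, j]} at gene "
                f"{self.gene_ids[i]!r}, cell {self.cell_ids[j]!r}"
            )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def gene_index(self, gene_id: str) -> int:
        try:
            return self._index[gene_id]
        except AttributeError:
            object.__setattr__(
                self, "_index", {g: i for i, g in enumerate(self.gene_ids)}
            )
            return self._index[gene_id]

    def row(self, gene_id: str) -> np.ndarray:
        """Expression profile of one gene across all cells."""
        if gene_id not in set(self.gene_ids):
            raise KeyError(f"gene {gene_id!r} not in expression matrix")
        return self.values[self.gene_index(gene_id)]

    def transpose_view(self) -> "ExpressionMatrix":
        return ExpressionMatrix(self.cell_ids, self.gene_ids, self.values.T)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.gene_ids), columns=list(self.cell_ids)
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ExpressionMatrix":
        return cls(
            tuple(map(str, frame.index)),
            tuple(map(str, frame.columns)),
            frame.to_numpy(dtype=float),
        )


@dataclass(frozen=True)
class GoldNetwork:
    """Directed TF -> target edge set defining the supervised positives.

    ``gene_universe`` is the set of genes eligible as candidate targets;
    every edge endpoint must belong to it.  Self-edges are kept only if the
    input contains them.
    """

    edges: frozenset[tuple[str, str]]
    gene_universe: frozenset[str]
    _out: dict = field(init=False, repr=False, compare=False, hash=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "edges", frozenset(self.edges))
        object.__setattr__(self, "gene_universe", frozenset(self.gene_universe))
        for tf, tg in self.edges:
            if tf not in self.gene_universe:
                raise ValueError(f"edge source {tf!r} not in gene universe")
            if tg not in self.gene_universe:
                raise ValueError(f"edge target {tg!r} not in gene universe")
        out: dict[str, set[str]] = {}
        for tf, tg in self.edges:
            out.setdefault(tf, set()).add(tg)
        object.__setattr__(self, "_out", out)

    @property
    def tf_set(self) -> frozenset[str]:
        return frozenset(self._out)

    def targets_of(self, tf: str) -> frozenset[str]:
        return frozenset(self._out.get(tf, set()))

    def out_degree(self, tf: str) -> int:
        return len(self._out.get(tf, ()))


def _check_unique(ids, kind: str) -> None:
    seen: set[str] = set()
    for name in ids:
        if name in seen:
            raise ValueError(f"duplicate {kind} id {name!r}")
        seen.add(name)


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_expression(
    path: str | Path, orientation: str = "genes_by_cells"
) -> ExpressionMatrix:
    """Read an expression matrix from delimited text or MatrixMarket.

    Parameters
    ----------
    path
        ``.tsv``/``.txt`` (tab) or ``.csv`` (comma) with a header row of
        cell ids and a first column of gene ids; or a ``.mtx`` file with
        ``<prefix>.genes.txt`` and ``<prefix>.cells.txt`` sidecars.
    orientation
        ``"genes_by_cells"`` (default) if file rows are genes, or
        ``"cells_by_genes"`` if file rows are cells (the matrix is
        transposed on read so the result is always genes x cells).
    """
    path = Path(path)
    if orientation not in ("genes_by_cells", "cells_by_genes"):
        raise ValueError(f"unknown orientation {orientation!r}")
    if not path.exists():
        raise FileNotFoundError(path)

    if path.suffix.lower() == ".mtx":
        row_ids, col_ids, values = _read_mtx(path)
    else:
        frame = pd.read_csv(path, sep=_sep_for(path), index_col=0, header=0)
        if frame.empty:
            raise ValueError(f"empty expression matrix in {path}")
        non_numeric = frame.select_dtypes(exclude=[np.number]).columns
        if len(non_numeric):
            col = non_numeric[0]
            bad_rows = frame.index[
                pd.to_numeric(frame[col], errors="coerce").isna()
            ].tolist()
            raise ValueError(
                f"non-numeric entry in column {col!r}, row(s) {bad_rows[:3]} of {path}"
            )
        if frame.isna().to_numpy().any():
            i, j = np.argwhere(frame.isna().to_numpy())[0]
            raise ValueError(
                f"missing value at row {frame.index[i]!r}, column "
                f"{frame.columns[j]!r} of {path} (missing values are not imputed)"
            )
        row_ids = tuple(map(str, frame.index))
        col_ids = tuple(map(str, frame.columns))
        values = frame.to_numpy(dtype=float)

    if orientation == "cells_by_genes":
        row_ids, col_ids, values = col_ids, row_ids, values.T
    return ExpressionMatrix(row_ids, col_ids, values)


def _read_mtx(path: Path):
    prefix = path.with_suffix("")
    genes_file = prefix.with_suffix(".genes.txt")
    cells_file = prefix.with_suffix(".cells.txt")
    for sidecar in (genes_file, cells_file):
        if not sidecar.exists():
            raise FileNotFoundError(
                f"MatrixMarket sidecar {sidecar} missing for {path}"
            )
    mat = scipy.io.mmread(path)
    if scipy.sparse.issparse(mat):
        mat = mat.toarray()
    genes = tuple(genes_file.read_text().split())
    cells = tuple(cells_file.read_text().split())
    return genes, cells, np.asarray(mat, dtype=float)


def write_expression(expr: ExpressionMatrix, path: str | Path) -> None:
    """Write genes x cells TSV/CSV (or .mtx with sidecars)."""
    path = Path(path)
    if path.suffix.lower() == ".mtx":
        scipy.io.mmwrite(path, scipy.sparse.csr_matrix(expr.values))
        prefix = path.with_suffix("")
        prefix.with_suffix(".genes.txt").write_text("\n".join(expr.gene_ids) + "\n")
        prefix.with_suffix(".cells.txt").write_text("\n".join(expr.cell_ids) + "\n")
    else:
        expr.to_frame().to_csv(path, sep=_sep_for(path))


def read_network(
    path: str | Path,
    gene_universe,
    strict: bool = True,
) -> GoldNetwork:
    """Read a two-column TF -> target edge list.

    Duplicate lines collapse (edges are a set).  Edges naming a gene outside
    ``gene_universe`` raise by default; with ``strict=False`` they are
    dropped with a warning.  An empty file yields an empty network with a
    logged warning.
    """
    path = Path(path)
    universe = frozenset(map(str, gene_universe))
    if not universe:
        raise ValueError("gene_universe must be nonempty")
    if not path.exists():
        raise FileNotFoundError(path)

    edges: set[tuple[str, str]] = set()
    sep = _sep_for(path)
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = [p for p in line.replace(sep, "\t").split("\t") if p != ""]
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected two columns, got {line!r}")
            tf, target = parts[0], parts[1]
            missing = [g for g in (tf, target) if g not in universe]
            if missing:
                if strict:
                    raise ValueError(
                        f"{path}:{lineno}: gene {missing[0]!r} not in the "
                        "expression gene universe"
                    )
                warnings.warn(
                    f"dropping edge ({tf}, {target}): {missing[0]!r} not in universe",
                    stacklevel=2,
                )
                continue
            edges.add((tf, target))
    if not edges:
        logger.warning("network file %s contains no edges", path)
    return GoldNetwork(frozenset(edges), universe)


def write_network(net: GoldNetwork, path: str | Path) -> None:
    path = Path(path)
    sep = _sep_for(path)
    with open(path, "w") as handle:
        for tf, target in sorted(net.edges):
            handle.write(f"{tf}{sep}{target}\n")


_EDGE_COLUMNS = ["tf", "target", "score", "label", "fold"]


def write_edge_scores(table: pd.DataFrame, path: str | Path) -> None:
    """Write a ranked edge table as TSV.

    Rows are sorted by score descending, ties broken by (tf, target)
    lexicographically; scores are printed to 6 decimal places so a
    write/read round trip reproduces the table at that precision.
    """
    path = Path(path)
    cols = [c for c in _EDGE_COLUMNS if c in table.columns]
    for required in ("tf", "target", "score"):
        if required not in table.columns:
            raise ValueError(f"edge table missing column {required!r}")
    out = table[cols].copy()
    if not np.isfinite(out["score"].to_numpy(dtype=float)).all():
        raise ValueError("edge table contains non-finite scores")
    out = out.sort_values(
        ["score", "tf", "target"], ascending=[False, True, True], kind="mergesort"
    )
    out["score"] = out["score"].map(lambda s: f"{s:.6f}")
    out.to_csv(path, sep="\t", index=False)


def read_edge_scores(path: str | Path) -> pd.DataFrame:
    """Read back a table written by :func:`write_edge_scores`."""
    path = Path(path)
    table = pd.read_csv(path, sep="\t", dtype={"tf": str, "target": str})
    for required in ("tf", "target", "score"):
        if required not in table.columns:
            raise ValueError(f"{path} missing column {required!r}")
    return table
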