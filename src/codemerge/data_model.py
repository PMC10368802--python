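"""Core containers, I/O for standard single-cell formats, and normalization.

The internal orientation is always cells x genes (T x F). MatrixMarket
triplets produced by the common 10x-style pipelines are genes x cells, so
the mtx reader transposes by default.
"""

from __future__ import annotations

import gzip
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.io import mmread, mmwrite

#: a gene is "expressed" in a cell when its stored value is strictly greater
#: than this threshold; shared by every module (scoring, markers, simulate).
EXPRESSION_THRESHOLD = 0.0

RAW_COUNTS = "raw_counts"
LOG_NORMALIZED = "log_normalized"
_LAYER_KINDS = (RAW_COUNTS, LOG_NORMALIZED)


class FormatError(ValueError):
    """Malformed or inconsistent input files."""


def _as_str_array(ids: Sequence[str]) -> np.ndarray:
    return np.asarray(list(ids), dtype=object)


def _check_unique(ids: np.ndarray, what: str) -> None:
    if len(set(ids)) != len(ids):
        dupes = pd.Series(ids).value_counts()
        dupes = list(dupes[dupes > 1].index[:5])
        raise ValueError(f"duplicate {what}: {dupes}")


@dataclass
class ExpressionMatrix:
    """A cells x genes expression matrix with identifiers.

    Parameters
    ----------
    values
        T x F non-negative matrix, dense ndarray or scipy sparse.
    cell_ids, gene_ids
        Ordered unique string identifiers for rows and columns.
    layer_kind
        Either ``"raw_counts"`` or ``"log_normalized"``.
    """

    values: np.ndarray | sparse.spmatrix
    cell_ids: np.ndarray
    gene_ids: np.ndarray
    layer_kind: str = RAW_COUNTS

    def __post_init__(self) -> None:
        self.cell_ids = _as_str_array(self.cell_ids)
        self.gene_ids = _as_str_array(self.gene_ids)
        if self.layer_kind not in _LAYER_KINDS:
            raise ValueError(f"layer_kind must be one of {_LAYER_KINDS}")
        t, f = self.shape
        if t < 1 or f < 1:
            raise ValueError("matrix must have at least one cell and one gene")
        if t != len(self.cell_ids) or f != len(self.gene_ids):
            raise FormatError(
                f"matrix shape {self.shape} does not match "
                f"{len(self.cell_ids)} cell ids x {len(self.gene_ids)} gene ids"
            )
        _check_unique(self.cell_ids, "cell_ids")
        _check_unique(self.gene_ids, "gene_ids")
        data = self.values.data if sparse.issparse(self.values) else self.values
        if data.size and np.min(data) < 0:
            raise ValueError("expression values must be non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def n_cells(self) -> int:
        return self.shape[0]

    @property
    def n_genes(self) -> int:
        return self.shape[1]

    def gene_index(self, genes: Sequence[str]) -> np.ndarray:
        """Column indices for gene ids; unknown ids raise ValueError."""
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        try:
            return np.array([lookup[g] for g in genes], dtype=int)
        except KeyError as exc:
            raise ValueError(f"unknown gene id: {exc.args[0]!r}") from None

    def dense(self) -> np.ndarray:
        """Values as a dense float64 ndarray (copy only if sparse)."""
        if sparse.issparse(self.values):
            return np.asarray(self.values.todense(), dtype=float)
        return np.asarray(self.values, dtype=float)

    def columns(self, genes: Sequence[str]) -> np.ndarray:
        """Dense T x len(genes) sub-matrix for the given genes."""
        idx = self.gene_index(genes)
        sub = self.values[:, idx]
        if sparse.issparse(sub):
            sub = np.asarray(sub.todense())
        return np.asarray(sub, dtype=float)

    def subset_cells(self, mask_or_index: np.ndarray) -> "ExpressionMatrix":
        vals = self.values[mask_or_index, :]
        return ExpressionMatrix(
            vals, self.cell_ids[mask_or_index], self.gene_ids, self.layer_kind
        )


@dataclass
class ClusterPartition:
    """One cluster label per cell, aligned with an ExpressionMatrix."""

    labels: np.ndarray
    cell_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.labels = _as_str_array(self.labels)
        if self.cell_ids is not None:
            self.cell_ids = _as_str_array(self.cell_ids)
            if len(self.cell_ids) != len(self.labels):
                raise ValueError("labels and cell_ids length mismatch")

    @property
    def clusters(self) -> list[str]:
        """Distinct labels, ordered by first appearance."""
        return list(pd.unique(self.labels))

    @property
    def n_cells(self) -> int:
        return len(self.labels)

    def indices(self, cluster: str) -> np.ndarray:
        return np.flatnonzero(self.labels == cluster)

    def sizes(self) -> dict[str, int]:
        return {c: int(np.sum(self.labels == c)) for c in self.clusters}

    def relabel(self, mapping: dict[str, str]) -> "ClusterPartition":
        new = np.array([mapping[l] for l in self.labels], dtype=object)
        return ClusterPartition(new, self.cell_ids)

    def subset(self, index: np.ndarray) -> "ClusterPartition":
        cid = None if self.cell_ids is None else self.cell_ids[index]
        return ClusterPartition(self.labels[index], cid)


@dataclass
class ScoreMatrix:
    """Cells x clusters enrichment scores."""

    values: np.ndarray
    cell_ids: np.ndarray
    cluster_ids: np.ndarray
    method: str = "code"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.cell_ids = _as_str_array(self.cell_ids)
        self.cluster_ids = _as_str_array(self.cluster_ids)
        if self.values.shape != (len(self.cell_ids), len(self.cluster_ids)):
            raise ValueError("score matrix shape does not match identifiers")

    def column(self, cluster: str) -> np.ndarray:
        pos = np.flatnonzero(self.cluster_ids == cluster)
        if pos.size == 0:
            raise ValueError(f"cluster {cluster!r} not present in score matrix")
        return self.values[:, pos[0]]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.cell_ids,
                            columns=self.cluster_ids)


# ---------------------------------------------------------------------------
# I/O


def _dedupe_ids(ids: list[str]) -> list[str]:
    """Disambiguate duplicates in file order: x, x-1, x-2, ..."""
    seen: dict[str, int] = {}
    out = []
    for g in ids:
        n = seen.get(g, 0)
        out.append(g if n == 0 else f"{g}-{n}")
        seen[g] = n + 1
    return out


def _find_component(directory: Path, stems: Sequence[str]) -> Path:
    for stem in stems:
        for name in (stem, stem + ".gz"):
            p = directory / name
            if p.exists():
                return p
    raise FileNotFoundError(
        f"missing component in {directory}: expected one of {list(stems)} "
        "(optionally gzipped)"
    )


def _read_id_column(path: Path) -> list[str]:
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        return [line.rstrip("\n").split("\t")[0] for line in fh if line.strip()]


def read_expression(
    path: str | os.PathLike,
    format: str | None = None,
    transpose: bool | None = None,
    layer_kind: str = RAW_COUNTS,
) -> ExpressionMatrix:
    """Read an expression matrix from mtx_dir, csv/tsv, or h5ad.

    ``format`` is inferred from the path when omitted (directory -> mtx_dir,
    .h5ad -> h5ad, else csv). MTX directories from the common pipelines are
    genes x cells, so transpose defaults to True for mtx_dir and False
    otherwise.
    """
    path = Path(path)
    if format is None:
        if path.is_dir():
            format = "mtx_dir"
        elif path.suffix == ".h5ad":
            format = "h5ad"
        else:
            format = "csv"

    if format == "mtx_dir":
        if not path.is_dir():
            raise FileNotFoundError(f"mtx_dir path is not a directory: {path}")
        mtx = _find_component(path, ["matrix.mtx"])
        genes = _find_component(path, ["features.tsv", "genes.tsv"])
        barcodes = _find_component(path, ["barcodes.tsv"])
        mat = mmread(os.fspath(mtx))
        if transpose is None or transpose:
            mat = mat.T
        mat = sparse.csr_matrix(mat)
        gene_ids = _dedupe_ids(_read_id_column(genes))
        cell_ids = _dedupe_ids(_read_id_column(barcodes))
        if mat.shape != (len(cell_ids), len(gene_ids)):
            raise FormatError(
                f"matrix shape {mat.shape} inconsistent with {len(cell_ids)} "
                f"barcodes x {len(gene_ids)} features"
            )
        return ExpressionMatrix(mat, cell_ids, gene_ids, layer_kind)

    if format == "csv":
        if not path.exists():
            raise FileNotFoundError(f"no such file: {path}")
        sep = "\t" if path.suffix in (".tsv", ".txt") else ","
        df = pd.read_csv(path, sep=sep, index_col=0)
        if transpose:
            df = df.T
        return ExpressionMatrix(
            df.to_numpy(dtype=float),
            _dedupe_ids([str(i) for i in df.index]),
            _dedupe_ids([str(c) for c in df.columns]),
            layer_kind,
        )

    if format == "h5ad":
        import anndata as ad

        if not path.exists():
            raise FileNotFoundError(f"no such file: {path}")
        adata = ad.read_h5ad(os.fspath(path))
        mat = adata.X
        if sparse.issparse(mat):
            mat = sparse.csr_matrix(mat)
        else:
            mat = np.asarray(mat)
        if transpose:
            mat = mat.T
        kind = adata.uns.get("layer_kind", layer_kind)
        return ExpressionMatrix(
            mat,
            _dedupe_ids([str(i) for i in adata.obs_names]),
            _dedupe_ids([str(i) for i in adata.var_names]),
            kind,
        )

    raise ValueError(f"unknown format: {format!r}")


def write_expression(expr: ExpressionMatrix, path: str | os.PathLike,
                     format: str | None = None) -> None:
    """Write to mtx_dir (genes x cells triplets + TSVs), csv, or h5ad."""
    path = Path(path)
    if format is None:
        if path.suffix == ".h5ad":
            format = "h5ad"
        elif path.suffix in (".csv", ".tsv"):
            format = "csv"
        else:
            format = "mtx_dir"

    if format == "mtx_dir":
        path.mkdir(parents=True, exist_ok=True)
        mmwrite(os.fspath(path / "matrix.mtx"),
                sparse.coo_matrix(expr.values).T)
        pd.Series(expr.gene_ids).to_csv(path / "features.tsv", sep="\t",
                                        header=False, index=False)
        pd.Series(expr.cell_ids).to_csv(path / "barcodes.tsv", sep="\t",
                                        header=False, index=False)
        return

    if format == "csv":
        sep = "\t" if path.suffix == ".tsv" else ","
        pd.DataFrame(expr.dense(), index=expr.cell_ids,
                     columns=expr.gene_ids).to_csv(path, sep=sep)
        return

    if format == "h5ad":
        import anndata as ad

        x = expr.values
        if not sparse.issparse(x):
            x = np.asarray(x, dtype=float)
        else:
            x = sparse.csr_matrix(x).astype(float)
        adata = ad.AnnData(
            X=x,
            obs=pd.DataFrame(index=pd.Index(expr.cell_ids, dtype=str)),
            var=pd.DataFrame(index=pd.Index(expr.gene_ids, dtype=str)),
        )
        adata.uns["layer_kind"] = expr.layer_kind
        adata.write_h5ad(os.fspath(path))
        return

    raise ValueError(f"unknown format: {format!r}")


def read_labels(path: str | os.PathLike, column: str | None = None,
                cell_ids: Sequence[str] | None = None) -> ClusterPartition:
    """Read cluster labels from a cell-metadata TSV/CSV (cell id in col 0).

    When ``cell_ids`` is given the labels are re-ordered to match it.
    """
    path = Path(path)
    sep = "\t" if path.suffix in (".tsv", ".txt") else ","
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    if column is None:
        column = df.columns[0]
    if column not in df.columns:
        raise ValueError(
            f"label field {column!r} not found; available: {list(df.columns)}"
        )
    if cell_ids is not None:
        missing = [c for c in cell_ids if c not in df.index]
        if missing:
            raise FormatError(f"labels missing for cells: {missing[:5]}")
        df = df.loc[list(cell_ids)]
    return ClusterPartition(df[column].to_numpy(), df.index.to_numpy())


def write_labels(partition: ClusterPartition, path: str | os.PathLike,
                 column: str = "cluster") -> None:
    ids = partition.cell_ids
    if ids is None:
        ids = np.array([f"cell{i}" for i in range(partition.n_cells)],
                       dtype=object)
    pd.DataFrame({column: partition.labels},
                 index=pd.Index(ids, name="cell")).to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Normalization


def log_normalize(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Median-total count normalization followed by log1p.

    Each cell is scaled so that its total equals the median per-cell total,
    then log(1 + x) is applied. Zeros are preserved exactly and the
    transform is strictly monotone within each cell.
    """
    if expr.layer_kind != RAW_COUNTS:
        raise ValueError("log_normalize expects a raw_counts matrix")
    if sparse.issparse(expr.values):
        totals = np.asarray(expr.values.sum(axis=1)).ravel()
    else:
        totals = np.asarray(expr.values, dtype=float).sum(axis=1)
    zero = totals <= 0
    if np.any(zero):
        bad = list(expr.cell_ids[zero][:10])
        raise ValueError(f"cells with zero total counts cannot be "
                         f"normalized: {bad}")
    median = float(np.median(totals))
    factors = median / totals
    if sparse.issparse(expr.values):
        scaled = sparse.diags(factors) @ expr.values.tocsr()
        scaled.data = np.log1p(scaled.data)
        out = scaled
    else:
        out = np.log1p(np.asarray(expr.values, dtype=float)
                       * factors[:, None])
    return ExpressionMatrix(out, expr.cell_ids, expr.gene_ids, LOG_NORMALIZED)
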