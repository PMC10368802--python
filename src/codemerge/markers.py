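"""One-versus-rest differential expression and marker gene set selection.

Marker genes per cluster are up to ``max_genes`` differentially upregulated
genes (BH-adjusted p < ``padj_cutoff``) ranked with Welch's t-statistic in a
one-versus-rest comparison on the log-normalized layer.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse, stats

from .data_model import ClusterPartition, ExpressionMatrix


@dataclass
class MarkerConfig:
    """Marker selection parameters.

    max_genes : keep at most this many markers per cluster (default 5).
    min_genes : guarantee at least this many, falling back to the top-ranked
        upregulated genes when too few pass the filters (default 1).
    padj_cutoff : BH-adjusted p-value threshold (default 0.05).
    rank_by : "t_stat" or "log_fc" (default "t_stat").
    t_threshold : optional minimum Welch t-statistic for a marker.
    """

    max_genes: int = 5
    min_genes: int = 1
    padj_cutoff: float = 0.05
    rank_by: str = "t_stat"
    t_threshold: float | None = None

    def __post_init__(self) -> None:
        if not (1 <= self.min_genes <= self.max_genes):
            raise ValueError("need 1 <= min_genes <= max_genes")
        if not (0 < self.padj_cutoff <= 1):
            raise ValueError("padj_cutoff must be in (0, 1]")
        if self.rank_by not in ("t_stat", "log_fc"):
            raise ValueError("rank_by must be 't_stat' or 'log_fc'")


@dataclass
class MarkerGeneSets:
    """Per-cluster ranked marker gene lists plus the full DE tables."""

    sets: dict[str, list[str]]
    tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def __getitem__(self, cluster: str) -> list[str]:
        return self.sets[cluster]

    def __contains__(self, cluster: str) -> bool:
        return cluster in self.sets

    @property
    def clusters(self) -> list[str]:
        return list(self.sets)

    def to_frame(self) -> pd.DataFrame:
        rows = [(c, g, r) for c, genes in self.sets.items()
                for r, g in enumerate(genes)]
        return pd.DataFrame(rows, columns=["cluster", "gene", "rank"])

    def to_dict(self) -> dict[str, list[str]]:
        return {c: list(g) for c, g in self.sets.items()}

    @classmethod
    def from_dict(cls, mapping: dict[str, list[str]]) -> "MarkerGeneSets":
        return cls({str(c): [str(g) for g in genes]
                    for c, genes in mapping.items()})

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "MarkerGeneSets":
        sets: dict[str, list[str]] = {}
        for c, sub in df.groupby("cluster", sort=False):
            if "rank" in sub.columns:
                sub = sub.sort_values("rank")
            sets[str(c)] = [str(g) for g in sub["gene"]]
        return cls(sets)


def bh_adjust(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, returned in input order."""
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvals must be a 1-D vector")
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    # enforce monotone non-decreasing from the largest rank downwards
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


def _grouped_sums(expr: ExpressionMatrix, partition: ClusterPartition
                  ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-cluster per-gene sums and sums of squares in one pass.

    Returns (sums, sq_sums, counts): C x F, C x F, and C arrays in
    partition.clusters order. Uses a sparse one-hot matmul rather than
    fancy-indexed sub-matrices, which would copy the matrix per cluster.
    """
    clusters = partition.clusters
    index = {c: i for i, c in enumerate(clusters)}
    rows = np.array([index[l] for l in partition.labels])
    onehot = sparse.csr_matrix(
        (np.ones(len(rows)), (rows, np.arange(len(rows)))),
        shape=(len(clusters), len(rows)),
    )
    x = expr.values
    if sparse.issparse(x):
        x = x.tocsr()
        sums = np.asarray((onehot @ x).todense())
        sq = np.asarray((onehot @ x.multiply(x)).todense())
    else:
        x = np.asarray(x, dtype=float)
        sums = onehot @ x
        sq = onehot @ (x * x)
    counts = np.bincount(rows, minlength=len(clusters)).astype(float)
    return sums, sq, counts


def _welch_from_sums(s1, q1, n1, s0, q0, n0):
    """Vectorized Welch t/p/log_fc from group sums and sums of squares."""
    m1, m0 = s1 / n1, s0 / n0
    v1 = np.maximum(q1 - n1 * m1 ** 2, 0.0) / max(n1 - 1, 1)
    v0 = np.maximum(q0 - n0 * m0 ** 2, 0.0) / max(n0 - 1, 1)
    se1, se0 = v1 / n1, v0 / n0
    denom = se1 + se0
    ok = denom > 0
    t = np.zeros(m1.shape)
    p = np.ones(m1.shape)
    t[ok] = (m1[ok] - m0[ok]) / np.sqrt(denom[ok])
    # Welch-Satterthwaite degrees of freedom
    with np.errstate(invalid="ignore", divide="ignore"):
        df = denom[ok] ** 2 / (se1[ok] ** 2 / (n1 - 1)
                               + se0[ok] ** 2 / (n0 - 1))
    p[ok] = 2 * stats.t.sf(np.abs(t[ok]), df)
    return t, p, m1 - m0


def _welch_tables(expr: ExpressionMatrix, partition: ClusterPartition
                  ) -> dict[str, pd.DataFrame]:
    """One-vs-rest Welch tables for every cluster from shared sums."""
    sums, sq, counts = _grouped_sums(expr, partition)
    tot_s, tot_q, tot_n = sums.sum(0), sq.sum(0), counts.sum()
    out = {}
    for idx, cluster in enumerate(partition.clusters):
        n1 = int(counts[idx])
        n0 = int(tot_n - n1)
        if n1 < 2 or n0 < 2:
            raise ValueError(
                f"cluster {cluster!r} or its complement has fewer than 2 "
                f"cells ({n1} vs {n0})"
            )
        t, p, log_fc = _welch_from_sums(sums[idx], sq[idx], n1,
                                        tot_s - sums[idx], tot_q - sq[idx],
                                        n0)
        out[cluster] = pd.DataFrame(
            {"t": t, "pval": p, "log_fc": log_fc},
            index=pd.Index(expr.gene_ids, name="gene"),
        )
    return out


def welch_one_vs_rest(expr: ExpressionMatrix, partition: ClusterPartition,
                      cluster: str) -> pd.DataFrame:
    """Two-sided Welch t-test of one cluster against all remaining cells.

    Returns a per-gene DataFrame with columns ``t``, ``pval``, ``log_fc``
    (difference of means on the log scale). Genes with zero pooled variance
    get t = 0, p = 1.
    """
    if cluster not in partition.clusters:
        raise ValueError(f"cluster {cluster!r} not in partition")
    two_way = ClusterPartition(
        np.where(partition.labels == cluster, cluster, "__rest__"),
        partition.cell_ids,
    )
    return _welch_tables(expr, two_way)[cluster]


def _rank_table(table: pd.DataFrame, rank_by: str) -> pd.DataFrame:
    """Deterministic ranking: rank_by desc, other stat desc, gene id asc."""
    primary = "t" if rank_by == "t_stat" else "log_fc"
    secondary = "log_fc" if primary == "t" else "t"
    return table.sort_values(
        [primary, secondary, "gene"], ascending=[False, False, True],
        kind="stable",
    )


def select_markers(expr: ExpressionMatrix, partition: ClusterPartition,
                   config: MarkerConfig | None = None) -> MarkerGeneSets:
    """Select up to ``max_genes`` upregulated marker genes per cluster.

    Genes must have positive log fold change and pass the BH-adjusted
    p-value cutoff (adjusted across all genes within each one-vs-rest
    comparison) and, if set, the t-statistic threshold. If fewer than
    ``min_genes`` pass, the top ``min_genes`` upregulated genes by rank are
    taken regardless of the filters, and a warning is recorded.
    """
    config = config or MarkerConfig()
    clusters = partition.clusters
    if len(clusters) < 2:
        raise ValueError("marker selection needs at least 2 clusters")
    sets: dict[str, list[str]] = {}
    tables: dict[str, pd.DataFrame] = {}
    notes: list[str] = []
    all_tables = _welch_tables(expr, partition)
    for cluster in clusters:
        table = all_tables[cluster].reset_index()
        table["padj"] = bh_adjust(table["pval"].to_numpy())
        up = table[table["log_fc"] > 0]
        if up.empty:
            raise ValueError(
                f"cluster {cluster!r} has no upregulated gene; it cannot be "
                "scored"
            )
        ranked = _rank_table(up, config.rank_by)
        passing = ranked[ranked["padj"] < config.padj_cutoff]
        if config.t_threshold is not None:
            passing = passing[passing["t"] > config.t_threshold]
        chosen = list(passing["gene"][: config.max_genes])
        if len(chosen) < config.min_genes:
            chosen = list(ranked["gene"][: config.min_genes])
            msg = (f"cluster {cluster!r}: only {len(passing)} genes passed "
                   f"the filters; fell back to the top {config.min_genes} "
                   "upregulated genes by rank")
            notes.append(msg)
            warnings.warn(msg)
        sets[cluster] = chosen
        tables[cluster] = table.set_index("gene")
    return MarkerGeneSets(sets, tables, notes)


def write_markers_tsv(markers: MarkerGeneSets, path) -> None:
    markers.to_frame().to_csv(path, sep="\t", index=False)


def read_markers(path) -> MarkerGeneSets:
    """Read marker sets from a two-column TSV (cluster, gene) or JSON."""
    import json
    from pathlib import Path

    path = Path(path)
    if path.suffix == ".json":
        with open(path) as fh:
            return MarkerGeneSets.from_dict(json.load(fh))
    df = pd.read_csv(path, sep="\t", dtype=str)
    return MarkerGeneSets.from_frame(df)
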